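"""Shared containers, errors and table schemas used across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class InvalidConfigError(ValueError):
    """A generator / analysis configuration violates its invariants."""


class InvalidSiteError(ValueError):
    """A chain node index is not a valid interior bending site."""


class PlacementError(RuntimeError):
    """A rendered object falls outside the image grid."""


class SchemaError(ValueError):
    """A table does not conform to the documented CSV schema."""


class SmallSampleError(ValueError):
    """Too few observations for the requested decomposition."""


class FitError(RuntimeError):
    """A nonlinear fit failed to converge or produced no estimate."""


#: Shared per-complex measurement schema.  Both the image pipeline
#: (trace -> detect -> measure) and the fast tabular generator emit this,
#: so the statistics layer is agnostic of the data source.
MEASUREMENT_COLUMNS = [
    "molecule_id",
    "position_pct_folded",
    "bend_angle_deg",
    "volume_nm3",
    "max_height_nm",
    "is_qd",
    "condition",
    "replicate",
]

#: Per-trace QC summary schema written by the tracing stage.
TRACE_COLUMNS = ["molecule_id", "contour_length_nm", "qc_status"]


@dataclass
class HeightMap:
    """An AFM topograph: heights in nm on a square-pixel grid.

    ``grid[i, j]`` is the height of the pixel whose centre sits at
    ``x = (j + 0.5) * pixel_size``, ``y = (i + 0.5) * pixel_size`` (nm).
    """

    grid: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise InvalidConfigError("height map must be a 2D array")
        if not np.all(np.isfinite(self.grid)):
            raise InvalidConfigError("height map contains non-finite values")
        if not self.pixel_size > 0:
            raise InvalidConfigError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def extent_nm(self) -> tuple[float, float]:
        """(width, height) of the imaged area in nm."""
        return (self.grid.shape[1] * self.pixel_size,
                self.grid.shape[0] * self.pixel_size)


def sample_height(height_map: HeightMap, points_nm: np.ndarray) -> np.ndarray:
    """Bilinearly interpolate heights at (x, y) positions given in nm."""
    from scipy.ndimage import map_coordinates

    pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
    px = height_map.pixel_size
    rows = pts[:, 1] / px - 0.5
    cols = pts[:, 0] / px - 0.5
    return map_coordinates(height_map.grid, [rows, cols], order=1,
                           mode="nearest")


def fold_position_pct(position_pct: np.ndarray | float):
    """Fold positions on [0, 100]% of DNA length to [0, 50]%.

    The two ends of a deposited DNA molecule are indistinguishable, so a
    position ``p`` and ``100 - p`` are equivalent; the distance to the
    nearer end is reported.
    """
    p = np.asarray(position_pct, dtype=float)
    folded = np.minimum(p, 100.0 - p)
    if np.isscalar(position_pct) or folded.ndim == 0:
        return float(folded)
    return folded


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Check a measurement table against the shared schema.

    Raises :class:`SchemaError` on missing columns or out-of-range values.
    NaN bend angles are allowed (angle undefined close to a DNA end).
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurement table missing columns: {missing}")
    if len(df):
        pos = df["position_pct_folded"].to_numpy(dtype=float)
        if np.any(pos < -1e-9) or np.any(pos > 50.0 + 1e-9):
            raise SchemaError("position_pct_folded must lie in [0, 50]")
        ang = df["bend_angle_deg"].to_numpy(dtype=float)
        ok = np.isnan(ang) | ((ang >= 0.0) & (ang < 180.0))
        if not np.all(ok):
            raise SchemaError("bend_angle_deg must lie in [0, 180) or be NaN")
        if np.any(df["volume_nm3"].to_numpy(dtype=float) < 0):
            raise SchemaError("volume_nm3 must be >= 0")
    return df
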