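"""Reading and writing of height maps and measurement tables.

Height maps travel as 32-bit float TIFF (nm) or whitespace-delimited
plain-text matrices, each with a small YAML sidecar recording pixel size
and seed so downstream stages need no extra arguments.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import HeightMap, SchemaError, validate_measurements

__all__ = [
    "write_height_map",
    "read_height_map",
    "sidecar_path",
    "write_measurements",
    "read_measurements",
]


def sidecar_path(path: Path | str) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".meta.yaml")


def write_height_map(height_map: HeightMap, path: Path | str,
                     seed: int | None = None) -> Path:
    """Write a height map as float32 TIFF (.tif/.tiff) or text matrix.

    A ``<name>.<ext>.meta.yaml`` sidecar records pixel size (nm), units
    and the generator seed if given.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, height_map.grid.astype(np.float32))
    else:
        np.savetxt(path, height_map.grid, fmt="%.6g")
    meta = {"pixel_size_nm": float(height_map.pixel_size),
            "height_units": "nm"}
    if seed is not None:
        meta["seed"] = int(seed)
    sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_height_map(path: Path | str,
                    pixel_size: float | None = None) -> HeightMap:
    """Read a TIFF or plain-matrix height map; pixel size comes from the
    sidecar unless given explicitly."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        grid = np.asarray(tifffile.imread(path), dtype=float)
    else:
        grid = np.loadtxt(path)
    if pixel_size is None:
        sc = sidecar_path(path)
        if not sc.exists():
            raise SchemaError(
                f"no pixel size given and sidecar {sc.name} not found")
        meta = yaml.safe_load(sc.read_text())
        pixel_size = float(meta["pixel_size_nm"])
    return HeightMap(grid=grid, pixel_size=pixel_size)


def write_measurements(df: pd.DataFrame, path: Path | str) -> Path:
    """Write a per-complex measurement table (validated) as CSV."""
    validate_measurements(df)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_measurements(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_measurements(df)
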