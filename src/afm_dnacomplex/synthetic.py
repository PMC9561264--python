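"""Synthetic AFM scenes of protein-DNA complexes with ground truth.

The generator emulates the imaging substrate of the study system: linear
505 bp DNA fragments (171.7 nm contour at 0.34 nm/bp) deposited on a flat
surface, carrying a specific binding site at 49.8% of the contour (and
optionally a second site at 51.8%, the E-box geometry), decorated with
protein blobs of defined volume and height, optionally quantum-dot (QD)
labelled complexes of greater height, imaged with Gaussian tip broadening
and additive pixel noise.

Two output modes exist:

* :func:`generate_scene` renders height maps plus a ground-truth table --
  the input for the full tracing/measurement pipeline;
* :func:`emit_measurement_table` samples per-complex measurement records
  directly from the configured distributions, bypassing imaging, with the
  same schema the measurement pipeline emits.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .chains import ChainConformation, impose_bend, sample_wlc_chain
from .core import (HeightMap, InvalidConfigError, PlacementError,
                   MEASUREMENT_COLUMNS, fold_position_pct)

__all__ = [
    "GeneratorConfig",
    "place_complexes",
    "render_scene",
    "generate_scene",
    "emit_measurement_table",
    "SyntheticScene",
    "qd_rendered_volume",
]

#: Ground-truth complex table schema.
TRUTH_COMPLEX_COLUMNS = [
    "molecule_id", "kind", "position_fraction", "bend_angle_true",
    "bend_direction", "volume_true", "is_qd",
]

#: Ground-truth molecule table schema.
TRUTH_MOLECULE_COLUMNS = [
    "molecule_id", "com_x_nm", "com_y_nm", "contour_length_nm",
    "n_complexes", "touches_border", "overlapping",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic scene generator.

    Defaults encode the study conditions: a 505 bp fragment with the
    lesion at 49.8% of the contour, specific occupancy 0.18 per DNA with
    a nonspecific background tuned to a specificity of roughly 540 (the
    reducing-condition regime), three bend-angle states at 0/35/70 deg,
    100 nm^3 protein complexes of 1.5 nm height and 4.5 nm QD labels.
    """

    n_molecules: int = 100
    dna_length_bp: int = 505
    rise_per_bp: float = 0.34                # nm per bp; 505 bp -> 171.7 nm
    persistence_length: float = 50.0         # nm, B-DNA on mica
    site_fraction: float = 0.498             # specific site, fraction of contour
    second_site_fraction: float | None = None  # e.g. 0.518 for the E-box
    occupancy_specific: float = 0.18         # Bernoulli per DNA, specific site
    occupancy_second: float = 0.0            # Bernoulli per DNA, second site
    nonspecific_rate: float = 0.17           # Poisson mean per DNA, uniform
    site_jitter_fraction: float = 0.015      # sd of specific-site placement
    bend_state_means: tuple[float, ...] = (0.0, 35.0, 70.0)   # deg
    bend_state_weights: tuple[float, ...] = (0.3, 0.4, 0.3)
    bend_state_sd: float = 8.0               # deg, within-state spread
    protein_volume_nm3: float = 100.0        # monomer volume
    volume_sd_nm3: float = 15.0              # molecule-to-molecule spread
    protein_height_nm: float = 1.5
    qd_height_nm: float = 4.5
    qd_sigma_nm: float = 2.0                 # lateral sd of the QD blob core
    height_sd_nm: float = 0.3                # spread of measured peak heights
    qd_probability: float = 0.0
    dna_height_nm: float = 0.5               # apparent ridge height
    dna_sigma_nm: float = 1.0                # lateral sd of the ridge core
    pixel_size_nm: float = 2.0
    tip_sigma_nm: float = 3.0                # Gaussian tip broadening
    noise_sd_nm: float = 0.1                 # additive pixel noise
    tile_nm: float = 280.0                   # one molecule per layout tile
    seed: int = 0
    condition: str = "reducing"
    replicate: str = "r1"

    def __post_init__(self) -> None:
        if self.n_molecules < 0:
            raise InvalidConfigError("n_molecules must be >= 0")
        for name in ("rise_per_bp", "persistence_length", "protein_volume_nm3",
                     "protein_height_nm", "qd_height_nm", "qd_sigma_nm",
                     "dna_height_nm", "dna_sigma_nm", "pixel_size_nm",
                     "tile_nm"):
            if not getattr(self, name) > 0:
                raise InvalidConfigError(f"{name} must be > 0")
        for name in ("occupancy_specific", "occupancy_second",
                     "qd_probability", "site_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        if self.second_site_fraction is not None and not (
                0.0 <= self.second_site_fraction <= 1.0):
            raise InvalidConfigError("second_site_fraction must lie in [0, 1]")
        for name in ("nonspecific_rate", "noise_sd_nm", "tip_sigma_nm",
                     "bend_state_sd", "volume_sd_nm3", "height_sd_nm",
                     "site_jitter_fraction"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if len(self.bend_state_means) != len(self.bend_state_weights):
            raise InvalidConfigError("bend state means/weights length mismatch")
        if abs(sum(self.bend_state_weights) - 1.0) > 1e-12:
            raise InvalidConfigError("bend_state_weights must sum to 1")
        if self.dna_length_bp < 2:
            raise InvalidConfigError("dna_length_bp must be >= 2")
        if self.protein_height_nm <= self.dna_height_nm or \
                self.qd_height_nm <= self.dna_height_nm:
            raise InvalidConfigError(
                "complex heights must exceed the DNA ridge height")

    @property
    def contour_length_nm(self) -> float:
        return self.dna_length_bp * self.rise_per_bp

    def with_(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticScene:
    """A rendered height map plus its ground truth."""

    height_map: HeightMap
    complexes: pd.DataFrame    # TRUTH_COMPLEX_COLUMNS (+ x_nm, y_nm, rendered)
    molecules: pd.DataFrame    # TRUTH_MOLECULE_COLUMNS
    config: GeneratorConfig


def qd_rendered_volume(config: GeneratorConfig) -> float:
    """Integrated volume of a rendered QD blob (nm^3).

    QD labels are specified by their apex height above the surface and
    lateral core size; the implied blob volume above the DNA ridge is
    2*pi*(h - h_dna)*(sigma^2 + tip_sigma^2).
    """
    return (2.0 * np.pi * (config.qd_height_nm - config.dna_height_nm)
            * (config.qd_sigma_nm ** 2 + config.tip_sigma_nm ** 2))


def _draw_bend(config: GeneratorConfig, rng: np.random.Generator):
    means = np.asarray(config.bend_state_means, dtype=float)
    state = rng.choice(len(means), p=np.asarray(config.bend_state_weights))
    angle = abs(rng.normal(means[state], config.bend_state_sd))
    return float(angle), int(state)


def _draw_volume(config: GeneratorConfig, is_qd: bool,
                 rng: np.random.Generator) -> float:
    mean = qd_rendered_volume(config) if is_qd else config.protein_volume_nm3
    return float(max(rng.normal(mean, config.volume_sd_nm3), 1.0))


def place_complexes(chains, config: GeneratorConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Draw bound complexes for each molecule.

    Specific events are Bernoulli(occupancy) per DNA, positioned at the
    configured site fraction with Gaussian jitter; nonspecific counts are
    Poisson(nonspecific_rate) with uniform positions on [0, 1].

    ``chains`` may be a list of chains or an integer molecule count.
    """
    n = chains if isinstance(chains, int) else len(chains)
    rows = []
    for mol in range(n):
        events = []  # (kind, fraction)
        if rng.random() < config.occupancy_specific:
            frac = rng.normal(config.site_fraction,
                              config.site_jitter_fraction)
            events.append(("specific", float(np.clip(frac, 0.01, 0.99))))
        if (config.second_site_fraction is not None
                and rng.random() < config.occupancy_second):
            frac = rng.normal(config.second_site_fraction,
                              config.site_jitter_fraction)
            events.append(("second", float(np.clip(frac, 0.01, 0.99))))
        for _ in range(rng.poisson(config.nonspecific_rate)):
            events.append(("nonspecific", float(rng.uniform(0.01, 0.99))))
        for kind, frac in events:
            angle, _state = _draw_bend(config, rng)
            is_qd = bool(rng.random() < config.qd_probability)
            rows.append({
                "molecule_id": mol,
                "kind": kind,
                "position_fraction": frac,
                "bend_angle_true": angle,
                "bend_direction": float(rng.choice((-1.0, 1.0))),
                "volume_true": _draw_volume(config, is_qd, rng),
                "is_qd": is_qd,
            })
    df = pd.DataFrame(rows, columns=TRUTH_COMPLEX_COLUMNS)
    return df


def _stamp_gaussian(field_arr: np.ndarray, cx: float, cy: float,
                    amplitude: float, sigma_nm: float, px: float) -> None:
    """Add a round Gaussian bump onto the grid."""
    half = max(int(math.ceil(5.0 * sigma_nm / px)), 2)
    ci, cj = int(cy / px), int(cx / px)
    i0, i1 = max(ci - half, 0), min(ci + half + 1, field_arr.shape[0])
    j0, j1 = max(cj - half, 0), min(cj + half + 1, field_arr.shape[1])
    if i0 >= i1 or j0 >= j1:
        return
    yy = (np.arange(i0, i1) + 0.5) * px - cy
    xx = (np.arange(j0, j1) + 0.5) * px - cx
    r2 = yy[:, None] ** 2 + xx[None, :] ** 2
    field_arr[i0:i1, j0:j1] += amplitude * np.exp(-r2 / (2.0 * sigma_nm ** 2))


def _protein_blob_shape(volume: float, peak_excess: float,
                        config: GeneratorConfig) -> tuple[float, float]:
    """Pre-blur (amplitude, sigma) so that after the tip blur the blob
    keeps integral ``volume`` and rises ``peak_excess`` above the ridge
    it sits on (making the apex the configured complex height)."""
    sigma_min = 0.5 * config.pixel_size_nm
    s2 = volume / (2.0 * np.pi * peak_excess) - config.tip_sigma_nm ** 2
    sigma0 = math.sqrt(max(s2, sigma_min ** 2))
    return volume / (2.0 * np.pi * sigma0 ** 2), sigma0


def _qd_blob_shape(config: GeneratorConfig) -> tuple[float, float]:
    """Pre-blur (amplitude, sigma) of a QD blob: post-blur apex is exact."""
    s0 = config.qd_sigma_nm
    excess = config.qd_height_nm - config.dna_height_nm
    amp = excess * (s0 ** 2 + config.tip_sigma_nm ** 2) / s0 ** 2
    return amp, s0


def _bend_chain(chain: ChainConformation, mol_complexes: pd.DataFrame,
                ) -> ChainConformation:
    for _, row in mol_complexes.sort_values("position_fraction").iterrows():
        node = int(round(row.position_fraction * chain.n_segments))
        node = min(max(node, 1), chain.n_segments - 1)
        chain = impose_bend(chain, node, row.bend_angle_true,
                            direction=row.bend_direction)
    return chain


def _chain_overlaps(placed: list[np.ndarray], min_dist_nm: float) -> np.ndarray:
    """Pairwise proximity flags between chains (True = overlapping)."""
    n = len(placed)
    flags = np.zeros(n, dtype=bool)
    boxes = [(p.min(axis=0) - min_dist_nm, p.max(axis=0) + min_dist_nm)
             for p in placed]
    trees = [cKDTree(p[::3]) for p in placed]
    for i in range(n):
        for j in range(i + 1, n):
            if (boxes[i][0] > boxes[j][1]).any() or \
               (boxes[j][0] > boxes[i][1]).any():
                continue
            d = trees[i].query_ball_tree(trees[j], r=min_dist_nm)
            if any(d):
                flags[i] = flags[j] = True
    return flags


def render_scene(chains: list[ChainConformation], complexes: pd.DataFrame,
                 config: GeneratorConfig, rng: np.random.Generator,
                 on_offgrid: str = "error") -> SyntheticScene:
    """Rasterise chains and complexes into a height map.

    The DNA backbone is deposited as a line-mass ridge and each complex
    as a round blob; pre-blur shapes are compensated for the Gaussian tip
    broadening so that post-blur blob peak heights match the configured
    protein/QD heights while integrated blob volumes equal the true
    volumes (the blur conserves integrals).  Additive Gaussian pixel
    noise is applied last.

    ``on_offgrid``: "error" raises :class:`PlacementError` for a blob
    centre outside the grid; "skip" leaves it out of the image but keeps
    it in the truth table with ``rendered = False``.
    """
    if on_offgrid not in ("error", "skip"):
        raise InvalidConfigError("on_offgrid must be 'error' or 'skip'")
    px = config.pixel_size_nm
    n = len(chains)
    k = max(int(math.ceil(math.sqrt(max(n, 1)))), 1)
    margin = 0.5 * config.tile_nm
    size_nm = k * config.tile_nm + 2.0 * margin
    npx = int(round(size_nm / px))
    deposit = np.zeros((npx, npx))
    blob_field = np.zeros((npx, npx))

    complexes = complexes.copy()
    complexes["x_nm"] = np.nan
    complexes["y_nm"] = np.nan
    complexes["rendered"] = False

    # Bend and place chains tile by tile.
    placed: list[np.ndarray] = []
    mol_rows = []
    sigma_ridge_total = math.hypot(config.dna_sigma_nm, config.tip_sigma_nm)
    lam = config.dna_height_nm * math.sqrt(2.0 * math.pi) * sigma_ridge_total
    for mol, chain in enumerate(chains):
        mine = complexes[complexes.molecule_id == mol]
        chain = _bend_chain(chain, mine)
        tile_i, tile_j = divmod(mol, k)
        centre = np.array([margin + (tile_j + 0.5) * config.tile_nm,
                           margin + (tile_i + 0.5) * config.tile_nm])
        nodes = chain.nodes - chain.nodes.mean(axis=0) + centre
        placed.append(nodes)

        inside = ((nodes > 2 * px) & (nodes < size_nm - 2 * px)).all(axis=1)
        touches_border = bool(~inside.all())
        # deposit ridge mass at nearest pixels (clipped to the grid)
        cols = np.clip((nodes[:, 0] / px).astype(int), 0, npx - 1)
        rows_ = np.clip((nodes[:, 1] / px).astype(int), 0, npx - 1)
        np.add.at(deposit, (rows_, cols),
                  lam * chain.segment_length / px ** 2)

        for idx, row in mine.iterrows():
            node = int(round(row.position_fraction * chain.n_segments))
            x, y = nodes[min(node, chain.n_segments)]
            off = not (0.0 <= x < size_nm and 0.0 <= y < size_nm)
            if off and on_offgrid == "error":
                raise PlacementError(
                    f"complex of molecule {mol} at ({x:.1f}, {y:.1f}) nm "
                    "falls outside the image grid")
            complexes.loc[idx, ["x_nm", "y_nm"]] = (x, y)
            if off:
                continue
            if row.is_qd:
                amp, sigma0 = _qd_blob_shape(config)
            else:
                amp, sigma0 = _protein_blob_shape(
                    row.volume_true,
                    config.protein_height_nm - config.dna_height_nm, config)
            _stamp_gaussian(blob_field, x, y, amp, sigma0, px)
            complexes.loc[idx, "rendered"] = True

        mol_rows.append({
            "molecule_id": mol,
            "com_x_nm": float(nodes[:, 0].mean()),
            "com_y_nm": float(nodes[:, 1].mean()),
            "contour_length_nm": chain.contour_length,
            "n_complexes": int(len(mine)),
            "touches_border": touches_border,
        })

    dna_field = gaussian_filter(deposit, config.dna_sigma_nm / px) \
        if n else deposit
    # complexes sit on top of the DNA: heights add, so the apex of a
    # protein/QD blob on the ridge equals the configured complex height
    pre = dna_field + blob_field
    grid = gaussian_filter(pre, config.tip_sigma_nm / px) \
        if config.tip_sigma_nm > 0 else pre
    if config.noise_sd_nm > 0:
        grid = grid + rng.normal(0.0, config.noise_sd_nm, grid.shape)

    molecules = pd.DataFrame(mol_rows, columns=[c for c in
                                                TRUTH_MOLECULE_COLUMNS
                                                if c != "overlapping"])
    if n:
        molecules["overlapping"] = _chain_overlaps(placed, min_dist_nm=4.0)
    else:
        molecules["overlapping"] = pd.Series(dtype=bool)
    return SyntheticScene(height_map=HeightMap(grid, px),
                          complexes=complexes, molecules=molecules,
                          config=config)


def generate_scene(config: GeneratorConfig,
                   rng: np.random.Generator | None = None,
                   on_offgrid: str = "skip") -> SyntheticScene:
    """Sample chains + complexes and render them in one call."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chains = [sample_wlc_chain(config, rng)
              for _ in range(config.n_molecules)]
    complexes = place_complexes(chains, config, rng)
    return render_scene(chains, complexes, config, rng,
                        on_offgrid=on_offgrid)


def emit_measurement_table(config: GeneratorConfig,
                           rng: np.random.Generator | None = None
                           ) -> pd.DataFrame:
    """Fast tabular mode: sample measurement records directly.

    Folded positions, bend angles, volumes, peak heights and QD flags are
    drawn from the configured distributions; the schema is identical to
    the tracing pipeline's output, so downstream statistics cannot tell
    the two apart.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = place_complexes(config.n_molecules, config, rng)
    if len(truth) == 0:
        return pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    heights = np.where(
        truth.is_qd.to_numpy(),
        rng.normal(config.qd_height_nm, config.height_sd_nm, len(truth)),
        rng.normal(config.protein_height_nm, config.height_sd_nm, len(truth)))
    df = pd.DataFrame({
        "molecule_id": truth.molecule_id,
        "position_pct_folded": fold_position_pct(
            100.0 * truth.position_fraction.to_numpy()),
        "bend_angle_deg": truth.bend_angle_true,
        "volume_nm3": truth.volume_true,
        "max_height_nm": heights,
        "is_qd": heights >= 3.0,
        "condition": config.condition,
        "replicate": config.replicate,
    })
    return df[MEASUREMENT_COLUMNS]
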