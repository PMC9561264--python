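"""Flattening, segmentation and contour tracing of AFM height maps.

The tracer reproduces the standard recipe for surface-deposited DNA:
per-scanline polynomial background removal, thresholding at a multiple
of the robust noise level, skeletonisation of each connected region,
spur pruning, end-to-end ordering of the skeleton, sub-pixel smoothing,
and tangent extrapolation of the chain ends (skeletonisation erodes the
ends by roughly the ridge half-width; along the ridge axis the blurred
height falls to half its plateau value exactly at the physical end, which
the extrapolation exploits).  Failures are encoded as QC statuses rather
than exceptions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import savgol_filter
from skimage.measure import label as sk_label
from skimage.morphology import skeletonize

from .core import HeightMap, InvalidConfigError

__all__ = [
    "HeightMap",
    "MoleculeTrace",
    "Region",
    "flatten",
    "robust_noise_sd",
    "segment_molecules",
    "trace_contour",
    "filter_traces",
    "trace_height_map",
]

QC_OK = "ok"
QC_CLOSED_LOOP = "closed_loop"
QC_BRANCHED = "branched"
QC_EDGE = "edge_touching"
QC_OFF_LENGTH = "off_length"


@dataclass
class Region:
    """One connected above-threshold region of a height map."""

    label: int
    mask: np.ndarray          # boolean, full image size
    touches_border: bool
    n_pixels: int


@dataclass
class MoleculeTrace:
    """A traced DNA contour with QC status.

    ``path`` holds ordered sub-pixel (x, y) points in nm at ~1 nm
    spacing; ``arclength`` is the cumulative polyline length.
    """

    path: np.ndarray
    arclength: np.ndarray
    contour_length: float
    qc_status: str
    molecule_label: int = -1

    def reversed(self) -> "MoleculeTrace":
        """Same contour walked from the other end."""
        rev = self.path[::-1].copy()
        seg = np.hypot(*np.diff(rev, axis=0).T)
        return MoleculeTrace(path=rev,
                             arclength=np.concatenate(([0.0], np.cumsum(seg))),
                             contour_length=self.contour_length,
                             qc_status=self.qc_status,
                             molecule_label=self.molecule_label)


def robust_noise_sd(grid: np.ndarray) -> float:
    """MAD-based noise estimate; molecules occupy few pixels, so the
    median absolute deviation reflects the background."""
    med = np.median(grid)
    return float(1.4826 * np.median(np.abs(grid - med)))


def flatten(height_map: HeightMap, polynomial_order: int = 1) -> HeightMap:
    """Subtract a per-scanline polynomial background.

    The fit uses only pixels below a molecule-exclusion threshold
    (median + 3 robust sd); a scanline with too few background pixels
    falls back to the global background fit with a warning.
    """
    if polynomial_order not in (0, 1, 2, 3):
        raise InvalidConfigError("polynomial order must be in {0,1,2,3}")
    grid = height_map.grid
    x = np.arange(grid.shape[1], dtype=float)
    x = (x - x.mean()) / max(x.std(), 1.0)

    def rowwise(g: np.ndarray, bg_mask: np.ndarray) -> tuple[np.ndarray, int]:
        gx = np.tile(x, (g.shape[0], 1))[bg_mask]
        gz = g[bg_mask]
        global_coef = np.polynomial.polynomial.polyfit(
            gx, gz, polynomial_order) if gz.size > polynomial_order + 1 \
            else np.zeros(polynomial_order + 1)
        out = np.empty_like(g)
        fell = 0
        for i in range(g.shape[0]):
            m = bg_mask[i]
            if m.sum() >= polynomial_order + 2:
                coef = np.polynomial.polynomial.polyfit(
                    x[m], g[i, m], polynomial_order)
            else:
                coef = global_coef
                fell += 1
            out[i] = g[i] - np.polynomial.polynomial.polyval(x, coef)
        return out, fell

    # pass 1: fit on everything to expose molecules in the residual
    rough, _ = rowwise(grid, np.ones_like(grid, dtype=bool))
    excl = np.median(rough) + 3.0 * max(robust_noise_sd(rough), 1e-12)
    bg_mask = rough <= excl
    # pass 2: refit using only background pixels
    out, fell_back = rowwise(grid, bg_mask)
    if fell_back:
        warnings.warn(f"{fell_back} scanline(s) had no background pixels; "
                      "used global background fit", stacklevel=2)
    out -= np.median(out[bg_mask])
    return HeightMap(grid=out, pixel_size=height_map.pixel_size)


def segment_molecules(height_map: HeightMap,
                      threshold_nm: float | None = None,
                      min_pixels: int = 15,
                      presmooth_nm: float = 2.0) -> list[Region]:
    """Connected regions above threshold, border-touching ones flagged.

    Thresholding runs on a lightly smoothed copy of the map (the raw
    heights are untouched) so pixel noise does not perforate the DNA
    ridge.  The default threshold is ``max(3 * robust noise sd, 0.1 nm)``
    above the background median — a floor is needed for noiseless
    synthetic scenes where the MAD vanishes.
    """
    from scipy.ndimage import gaussian_filter
    from skimage.morphology import remove_small_holes

    grid = height_map.grid
    if presmooth_nm > 0:
        grid = gaussian_filter(grid, presmooth_nm / height_map.pixel_size)
    if threshold_nm is None:
        threshold_nm = max(3.0 * robust_noise_sd(grid), 0.1)
    mask = grid > (np.median(grid) + threshold_nm)
    # close noise pinholes in the ridge without filling genuine loops
    mask = remove_small_holes(mask, max_size=16)
    labels = sk_label(mask, connectivity=2)
    regions = []
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        n = int(m.sum())
        if n < min_pixels:
            continue
        rows, cols = np.nonzero(m)
        touches = bool(rows.min() == 0 or cols.min() == 0
                       or rows.max() == grid.shape[0] - 1
                       or cols.max() == grid.shape[1] - 1)
        regions.append(Region(label=lab, mask=m, touches_border=touches,
                              n_pixels=n))
    return regions


def _adjacency(coords: np.ndarray) -> dict[tuple[int, int], list]:
    """8-adjacency between skeleton pixels, with redundant diagonal edges
    (those bridged by a shared 4-neighbour) removed so that a clean path
    has node degrees <= 2."""
    pixset = set(map(tuple, coords))
    adj: dict[tuple[int, int], list] = {p: [] for p in pixset}
    for p in pixset:
        r, c = p
        for dr, dc in ((-1, -1), (-1, 0), (-1, 1), (0, -1),
                       (0, 1), (1, -1), (1, 0), (1, 1)):
            q = (r + dr, c + dc)
            if q not in pixset:
                continue
            if dr != 0 and dc != 0:
                # diagonal edge is redundant if a shared 4-neighbour exists
                if ((r, c + dc) in pixset) or ((r + dr, c) in pixset):
                    continue
            adj[p].append(q)
    return adj


def _prune_spurs(adj: dict, max_len: int) -> dict:
    """Iteratively delete side branches shorter than ``max_len`` pixels."""
    for _ in range(8):
        endpoints = [p for p, nb in adj.items() if len(nb) == 1]
        removed_any = False
        for ep in endpoints:
            if ep not in adj or len(adj[ep]) != 1:
                continue
            branch = [ep]
            prev, cur = ep, adj[ep][0]
            while len(adj[cur]) == 2 and len(branch) <= max_len:
                nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
                branch.append(cur)
                prev, cur = cur, nxt
            if len(adj[cur]) > 2 and len(branch) <= max_len:
                for p in branch:
                    for q in adj.pop(p, []):
                        if q in adj and p in adj[q]:
                            adj[q].remove(p)
                removed_any = True
        if not removed_any:
            break
    return adj


def _order_path(adj: dict) -> tuple[np.ndarray | None, str]:
    """Walk the pruned skeleton end to end; topology decides the status."""
    if not adj:
        return None, QC_BRANCHED
    degrees = [len(nb) for nb in adj.values()]
    endpoints = [p for p, nb in adj.items() if len(nb) == 1]
    if max(degrees) > 2 or len(endpoints) > 2:
        return None, QC_BRANCHED
    if len(endpoints) == 0:
        return None, QC_CLOSED_LOOP
    if len(endpoints) != 2:
        return None, QC_BRANCHED
    start = min(endpoints)  # deterministic orientation
    path = [start]
    prev, cur = None, start
    while True:
        nxt = [q for q in adj[cur] if q != prev]
        if not nxt:
            break
        prev, cur = cur, nxt[0]
        path.append(cur)
    if len(path) != len(adj):
        return None, QC_BRANCHED
    return np.asarray(path, dtype=float), QC_OK


def _extend_end(path_nm: np.ndarray, height_map: HeightMap,
                at_start: bool, max_ext_nm: float = 12.0,
                step_nm: float = 0.5) -> np.ndarray:
    """Extrapolate one chain end along its tangent until the height drops
    below half the local ridge height."""
    pts = path_nm[::-1] if at_start else path_nm
    k = min(5, len(pts) - 1)
    tangent = pts[-1] - pts[-1 - k]
    norm = np.hypot(*tangent)
    if norm < 1e-9:
        return path_nm
    tangent = tangent / norm
    px = height_map.pixel_size

    def h_at(p):
        return float(map_coordinates(height_map.grid,
                                     [[p[1] / px - 0.5], [p[0] / px - 0.5]],
                                     order=1, mode="nearest")[0])

    ref = h_at(pts[-1])
    if ref <= 0:
        return path_nm
    new_pts = []
    p = pts[-1].copy()
    travelled = 0.0
    w, h_ext = height_map.extent_nm
    while travelled < max_ext_nm:
        cand = p + step_nm * tangent
        if not (0 <= cand[0] < w and 0 <= cand[1] < h_ext):
            break
        if h_at(cand) < 0.5 * ref:
            break
        p = cand
        travelled += step_nm
        new_pts.append(p.copy())
    if not new_pts:
        return path_nm
    ext = np.asarray(new_pts)
    if at_start:
        return np.vstack((ext[::-1], path_nm))
    return np.vstack((path_nm, ext))


def _resample(path_nm: np.ndarray, step_nm: float = 1.0) -> np.ndarray:
    seg = np.hypot(*np.diff(path_nm, axis=0).T)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    if s[-1] <= step_nm:
        return path_nm
    si = np.arange(0.0, s[-1], step_nm)
    si = np.append(si, s[-1])
    return np.column_stack((np.interp(si, s, path_nm[:, 0]),
                            np.interp(si, s, path_nm[:, 1])))


def trace_contour(region: Region, height_map: HeightMap,
                  prune_len_nm: float = 12.0,
                  smooth_window: int = 5,
                  end_extension_nm: float = 12.0) -> MoleculeTrace:
    """Skeletonise a region and order it into a sub-pixel contour.

    QC statuses: ``branched`` (more than two endpoints after pruning),
    ``closed_loop`` (no endpoints), ``edge_touching`` (region on the
    image border), else ``ok``.
    """
    px = height_map.pixel_size
    skel = skeletonize(region.mask)
    coords = np.column_stack(np.nonzero(skel))
    if coords.shape[0] < 3:
        return MoleculeTrace(path=np.empty((0, 2)), arclength=np.empty(0),
                             contour_length=0.0, qc_status=QC_BRANCHED,
                             molecule_label=region.label)
    adj = _adjacency(coords)
    adj = _prune_spurs(adj, max_len=max(int(round(prune_len_nm / px)), 1))
    path_px, status = _order_path(adj)
    if region.touches_border:
        status = QC_EDGE
    if path_px is None or len(path_px) < 3:
        return MoleculeTrace(path=np.empty((0, 2)), arclength=np.empty(0),
                             contour_length=0.0, qc_status=status,
                             molecule_label=region.label)
    # pixel indices (row, col) -> (x, y) nm at pixel centres
    path_nm = np.column_stack(((path_px[:, 1] + 0.5) * px,
                               (path_px[:, 0] + 0.5) * px))
    win = min(smooth_window if smooth_window % 2 else smooth_window + 1,
              len(path_nm) - (1 - len(path_nm) % 2))
    if win >= 5:
        path_nm = savgol_filter(path_nm, win, polyorder=2, axis=0,
                                mode="interp")
    path_nm = _resample(path_nm, step_nm=1.0)
    if status == QC_OK and end_extension_nm > 0:
        path_nm = _extend_end(path_nm, height_map, at_start=True,
                              max_ext_nm=end_extension_nm)
        path_nm = _extend_end(path_nm, height_map, at_start=False,
                              max_ext_nm=end_extension_nm)
        path_nm = _resample(path_nm, step_nm=1.0)
    seg = np.hypot(*np.diff(path_nm, axis=0).T)
    arclength = np.concatenate(([0.0], np.cumsum(seg)))
    return MoleculeTrace(path=path_nm, arclength=arclength,
                         contour_length=float(arclength[-1]),
                         qc_status=status, molecule_label=region.label)


def filter_traces(traces: list[MoleculeTrace], expected_length_nm: float,
                  tolerance_fraction: float = 0.2) -> list[MoleculeTrace]:
    """Flag ok traces whose contour length is outside the expected band."""
    if not 0 < tolerance_fraction < 1:
        raise InvalidConfigError("tolerance_fraction must lie in (0, 1)")
    out = []
    for t in traces:
        if (t.qc_status == QC_OK and
                abs(t.contour_length - expected_length_nm)
                > tolerance_fraction * expected_length_nm):
            t = MoleculeTrace(path=t.path, arclength=t.arclength,
                              contour_length=t.contour_length,
                              qc_status=QC_OFF_LENGTH,
                              molecule_label=t.molecule_label)
        out.append(t)
    return out


def trace_height_map(height_map: HeightMap,
                     threshold_nm: float | None = None,
                     expected_length_nm: float | None = None,
                     tolerance_fraction: float = 0.2,
                     flatten_order: int | None = None,
                     **trace_kwargs) -> list[MoleculeTrace]:
    """Segment and trace every molecule in a height map.

    Set ``flatten_order`` to run background removal first; pass
    ``expected_length_nm`` to apply the full-length substrate filter.
    """
    if flatten_order is not None:
        height_map = flatten(height_map, flatten_order)
    regions = segment_molecules(height_map, threshold_nm)
    traces = [trace_contour(r, height_map, **trace_kwargs) for r in regions]
    if expected_length_nm is not None:
        traces = filter_traces(traces, expected_length_nm, tolerance_fraction)
    return traces
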