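"""Detection and measurement of protein complexes on traced DNA.

For every bound complex the pipeline reports the quantities single-
molecule AFM studies of protein-DNA interactions are built on: the
fractional position along the contour (folded to [0, 50]% because the
two DNA ends are indistinguishable), the DNA bend angle at the complex,
the complex volume above the local background, the maximum height, and a
quantum-dot flag from the >= 3 nm height criterion that separates
QD-labelled complexes (~4.5 nm) from bare protein (~1.5 nm).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, label as nd_label
from scipy.signal import find_peaks

from .core import HeightMap, MEASUREMENT_COLUMNS, sample_height
from .tracing import MoleculeTrace, QC_OK

__all__ = [
    "ComplexDetection",
    "VolumeResult",
    "detect_complexes",
    "fractional_position",
    "measure_bend_angle",
    "measure_volume",
    "classify_qd",
    "measure_traces",
]

QD_HEIGHT_CUTOFF_NM = 3.0


@dataclass(frozen=True)
class ComplexDetection:
    """One peak along a DNA contour."""

    arclength_nm: float
    position_nm: np.ndarray      # (x, y)
    peak_height_nm: float        # max height near the peak
    baseline_nm: float           # local DNA ridge level


@dataclass(frozen=True)
class VolumeResult:
    volume_nm3: float
    background_nm: float
    footprint_px: int
    ambiguous: bool


def _profile_along(trace: MoleculeTrace, height_map: HeightMap
                   ) -> tuple[np.ndarray, np.ndarray]:
    heights = sample_height(height_map, trace.path)
    return trace.arclength, heights


def detect_complexes(trace: MoleculeTrace, height_map: HeightMap,
                     min_peak_height_nm: float = 0.4,
                     nms_window_nm: float = 10.0) -> list[ComplexDetection]:
    """Local height maxima along the contour exceeding the DNA ridge.

    The ridge baseline is the median of the height profile; peaks must
    exceed it by ``min_peak_height_nm`` and are non-maximum-suppressed
    within ``nms_window_nm``.  Zero peaks is a valid outcome.
    """
    if trace.qc_status != QC_OK or len(trace.path) < 5:
        return []
    s, h = _profile_along(trace, height_map)
    baseline = float(np.median(h))
    ds = max(np.median(np.diff(s)), 1e-6)
    idx, _ = find_peaks(h, height=baseline + min_peak_height_nm,
                        distance=max(int(round(nms_window_nm / ds)), 1))
    out = []
    for i in idx:
        p = trace.path[i]
        # refine the height as the max in a small disk around the peak
        px = height_map.pixel_size
        offs = np.linspace(-1.5 * px, 1.5 * px, 7)
        xs, ys = np.meshgrid(p[0] + offs, p[1] + offs)
        peak_h = float(sample_height(
            height_map, np.column_stack((xs.ravel(), ys.ravel()))).max())
        out.append(ComplexDetection(arclength_nm=float(s[i]),
                                    position_nm=p.copy(),
                                    peak_height_nm=peak_h,
                                    baseline_nm=baseline))
    return out


def fractional_position(trace: MoleculeTrace,
                        peak_arclength_nm: float) -> float:
    """100 * min(d_end1, d_end2) / contour_length, in [0, 50]."""
    L = trace.contour_length
    s = float(np.clip(peak_arclength_nm, 0.0, L))
    return 100.0 * min(s, L - s) / L


def _fit_arm_direction(points: np.ndarray, origin: np.ndarray) -> np.ndarray:
    """Total-least-squares line direction, oriented away from the peak."""
    centred = points - points.mean(axis=0)
    cov = centred.T @ centred
    _w, v = np.linalg.eigh(cov)
    direction = v[:, -1]
    far = points[np.argmax(np.hypot(*(points - origin).T))]
    if direction @ (far - origin) < 0:
        direction = -direction
    return direction


def measure_bend_angle(trace: MoleculeTrace, peak_arclength_nm: float,
                       arm_length_nm: float = 10.0,
                       gap_nm: float = 0.0) -> float | None:
    """DNA bend angle at a complex from straight-line fits to both arms.

    Lines are fit to the contour over [peak - gap - arm, peak - gap) and
    (peak + gap, peak + gap + arm]; the bend is 180 deg minus the angle
    between the outward arm directions, so collinear arms give 0.  A
    nonzero ``gap_nm`` skips the contour segment occluded by the complex
    footprint itself (useful on traced images, where the skeleton through
    the blob is rounded).  Returns None when the peak is closer than
    gap + arm length to either end (the angle is geometrically undefined
    there).
    """
    L = trace.contour_length
    s0 = peak_arclength_nm
    reach = arm_length_nm + gap_nm
    if s0 < reach or s0 > L - reach:
        return None
    s = trace.arclength
    up = trace.path[(s >= s0 - reach) & (s < s0 - gap_nm)]
    down = trace.path[(s > s0 + gap_nm) & (s <= s0 + reach)]
    if len(up) < 3 or len(down) < 3:
        return None
    origin = trace.path[np.argmin(np.abs(s - s0))]
    d_up = _fit_arm_direction(up, origin)
    d_down = _fit_arm_direction(down, origin)
    cosang = np.clip(d_up @ d_down, -1.0, 1.0)
    between = np.degrees(np.arccos(cosang))
    return float(180.0 - between)


def _trace_samples_in(trace: MoleculeTrace, mask: np.ndarray,
                      origin_px: tuple[int, int], px: float) -> np.ndarray:
    """Boolean flag per trace sample: does it fall in the footprint mask?"""
    rows = (trace.path[:, 1] / px - origin_px[0]).astype(int)
    cols = (trace.path[:, 0] / px - origin_px[1]).astype(int)
    ok = (rows >= 0) & (rows < mask.shape[0]) & \
         (cols >= 0) & (cols < mask.shape[1])
    inside = np.zeros(len(trace.path), dtype=bool)
    inside[ok] = mask[rows[ok], cols[ok]]
    return inside


def _ridge_line_density(trace: MoleculeTrace, height_map: HeightMap,
                        s_lo: float, s_hi: float, background: float,
                        exclude: np.ndarray | None = None,
                        half_width_nm: float = 8.0) -> float | None:
    """Median DNA cross-section integral (nm^2) from perpendicular strips
    sampled at arclengths flanking a complex footprint."""
    s = trace.arclength
    strips = []
    offsets = np.arange(-half_width_nm, half_width_nm + 0.5, 1.0)
    for window in ((max(s_lo - 20.0, 2.0), s_lo - 4.0),
                   (s_hi + 4.0, min(s_hi + 20.0, s[-1] - 2.0))):
        for sv in np.arange(window[0], window[1], 2.0):
            i = int(np.argmin(np.abs(s - sv)))
            if exclude is not None and exclude[i]:
                continue
            if i < 1 or i > len(s) - 2:
                continue
            t = trace.path[i + 1] - trace.path[i - 1]
            n = np.hypot(*t)
            if n < 1e-9:
                continue
            normal = np.array([-t[1], t[0]]) / n
            pts = trace.path[i] + offsets[:, None] * normal[None, :]
            h = sample_height(height_map, pts)
            strips.append(float(np.sum(h - background) * 1.0))
    if not strips:
        return None
    return float(np.median(strips))


def measure_volume(height_map: HeightMap, detection: ComplexDetection,
                   trace: MoleculeTrace | None = None,
                   other_peaks: list[ComplexDetection] | None = None,
                   box_half_nm: float = 22.0,
                   dilation_nm: float = 8.0) -> VolumeResult:
    """Complex volume by summation above the local background.

    A half-prominence threshold seeds the connected footprint around the
    peak, which is then dilated to recover the blob tails; the background
    is the median height of an annulus around the footprint.  When the
    trace is given, the DNA ridge contribution inside the footprint is
    removed using the ridge cross-section measured on flanking strips.
    A footprint containing another detected peak is flagged ambiguous.
    """
    px = height_map.pixel_size
    grid = height_map.grid
    x, y = detection.position_nm
    r0, c0 = int(y / px), int(x / px)
    half = max(int(round(box_half_nm / px)), 3)
    i0, i1 = max(r0 - half, 0), min(r0 + half + 1, grid.shape[0])
    j0, j1 = max(c0 - half, 0), min(c0 + half + 1, grid.shape[1])
    sub = grid[i0:i1, j0:j1]
    if sub.size == 0:
        return VolumeResult(0.0, 0.0, 0, False)
    yy, xx = np.mgrid[i0:i1, j0:j1]
    rr = np.hypot(yy - y / px + 0.5, xx - x / px + 0.5) * px
    ring0 = rr > 0.8 * box_half_nm
    bg0 = float(np.median(sub[ring0])) if ring0.any() else float(np.median(sub))
    prominence = detection.peak_height_nm - bg0
    if prominence <= 0:
        return VolumeResult(0.0, bg0, 0, False)
    seed_mask = sub >= bg0 + 0.5 * prominence
    labels, _n = nd_label(seed_mask)
    pr, pc = r0 - i0, c0 - j0
    pr = min(max(pr, 0), sub.shape[0] - 1)
    pc = min(max(pc, 0), sub.shape[1] - 1)
    lab = labels[pr, pc]
    if lab == 0:
        # peak pixel below threshold (noise); take the nearest component
        cand = np.argwhere(labels > 0)
        if len(cand) == 0:
            return VolumeResult(0.0, bg0, 0, False)
        nearest = cand[np.argmin(np.hypot(*(cand - [pr, pc]).T))]
        lab = labels[tuple(nearest)]
    comp = labels == lab
    dil = max(int(round(dilation_nm / px)), 1)
    footprint = binary_dilation(comp, iterations=dil)
    annulus = binary_dilation(footprint, iterations=3) & \
        ~binary_dilation(footprint, iterations=1)
    background = float(np.median(sub[annulus])) if annulus.any() else bg0
    volume = float(np.sum(sub[footprint] - background) * px * px)

    if trace is not None and len(trace.path):
        inside = _trace_samples_in(trace, footprint, (i0, j0), px)
        if inside.any():
            s = trace.arclength
            s_in = s[inside]
            length_in = float(s_in.max() - s_in.min())
            lam = _ridge_line_density(trace, height_map,
                                      float(s_in.min()), float(s_in.max()),
                                      background, exclude=inside)
            if lam is not None and lam > 0 and length_in > 0:
                volume -= lam * length_in

    ambiguous = False
    if other_peaks:
        for op in other_peaks:
            if np.allclose(op.position_nm, detection.position_nm):
                continue
            orr = int(op.position_nm[1] / px) - i0
            occ = int(op.position_nm[0] / px) - j0
            if (0 <= orr < footprint.shape[0]
                    and 0 <= occ < footprint.shape[1]
                    and footprint[orr, occ]):
                ambiguous = True
    return VolumeResult(volume_nm3=max(volume, 0.0), background_nm=background,
                        footprint_px=int(footprint.sum()), ambiguous=ambiguous)


def classify_qd(max_height_nm: float,
                cutoff_nm: float = QD_HEIGHT_CUTOFF_NM) -> bool:
    """QD-labelled if the peak height reaches the cutoff (inclusive)."""
    return bool(max_height_nm >= cutoff_nm)


def measure_traces(height_map: HeightMap, traces: list[MoleculeTrace],
                   condition: str = "", replicate: str = "",
                   min_peak_height_nm: float = 0.4,
                   arm_length_nm: float = 10.0,
                   gap_nm: float = 5.0,
                   qd_cutoff_nm: float = QD_HEIGHT_CUTOFF_NM,
                   measure_volumes: bool = True
                   ) -> tuple[pd.DataFrame, int]:
    """Run detection + measurement over all ok traces.

    Returns the measurement table (shared schema) and the number of DNA
    molecules analysed (ok traces), the denominator of per-DNA
    statistics.  Peaks too close to an end for the bend angle keep their
    position record with NaN angle.
    """
    rows = []
    n_dna = 0
    for t in traces:
        if t.qc_status != QC_OK:
            continue
        n_dna += 1
        peaks = detect_complexes(t, height_map, min_peak_height_nm)
        for det in peaks:
            angle = measure_bend_angle(t, det.arclength_nm, arm_length_nm,
                                       gap_nm)
            if measure_volumes:
                vol = measure_volume(height_map, det, trace=t,
                                     other_peaks=peaks)
                volume = vol.volume_nm3
            else:
                volume = np.nan
            rows.append({
                "molecule_id": t.molecule_label,
                "position_pct_folded": fractional_position(
                    t, det.arclength_nm),
                "bend_angle_deg": np.nan if angle is None else angle,
                "volume_nm3": volume,
                "max_height_nm": det.peak_height_nm,
                "is_qd": classify_qd(det.peak_height_nm, qd_cutoff_nm),
                "condition": condition,
                "replicate": replicate,
            })
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    return df, n_dna
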