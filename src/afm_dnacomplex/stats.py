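"""Binding statistics from per-complex measurements.

Turns measurement tables into the headline single-molecule statistics:
folded position histograms normalised per DNA, Gaussian fits of the
specific-site peak over a flat nonspecific background, the binding
specificity

    S = N * (A_sp / A_nsp) + 1

with N the number of available binding sites (505 bp for the standard
substrate), occupancy of the specific bin (45-50% of DNA length) per
DNA molecule, Gaussian decomposition of bend-angle distributions, and
two-tailed pooled-variance t-tests between triplicate experiments
(df = 4 for two groups of three).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chisquare, norm, t as t_dist

from .core import (FitError, InvalidConfigError, SmallSampleError)

__all__ = [
    "PositionHistogram",
    "GaussianFitResult",
    "SpecificityResult",
    "ReplicateComparison",
    "build_position_histogram",
    "fit_position_model",
    "specificity",
    "specificity_from_fit",
    "occupancy_at_site",
    "decompose_bend_states",
    "compare_replicates",
    "N_SITES_DEFAULT",
]

N_SITES_DEFAULT = 505
SPECIFIC_BIN = (45.0, 50.0)


@dataclass(frozen=True)
class PositionHistogram:
    """Folded-position histogram on [0, 50]% of DNA length."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_dna: int

    @property
    def counts_per_dna(self) -> np.ndarray:
        return self.counts / self.n_dna

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class GaussianFitResult:
    """Gaussian components (center, sd, area-in-counts) over a constant
    background, from bounded least squares on histogram counts."""

    components: tuple[tuple[float, float, float], ...]
    background_level: float
    residual_rss: float
    success: bool = True
    message: str = ""


@dataclass(frozen=True)
class SpecificityResult:
    S: float
    A_sp: float
    A_nsp: float
    N: int
    occupancy_per_dna: float
    sd_over_replicates: float | None = None


@dataclass(frozen=True)
class ReplicateComparison:
    t_statistic: float
    degrees_freedom: int
    p_value: float
    stars: str
    infinite_t: bool = False


def build_position_histogram(measurements, bin_width_pct: float = 2.0,
                             n_dna: int | None = None) -> PositionHistogram:
    """Histogram folded positions into fixed bins [0, bw, ..., 50].

    ``measurements`` is a measurement table or an array of folded
    positions; numpy's right-inclusive last bin puts events at exactly
    50% into the top bin.
    """
    if isinstance(measurements, pd.DataFrame):
        positions = measurements["position_pct_folded"].to_numpy(dtype=float)
    else:
        positions = np.asarray(measurements, dtype=float)
    if n_dna is None or n_dna <= 0:
        raise InvalidConfigError("n_dna must be a positive count")
    nbins = int(round(50.0 / bin_width_pct))
    if abs(nbins * bin_width_pct - 50.0) > 1e-9:
        raise InvalidConfigError("bin width must divide 50% evenly")
    edges = np.linspace(0.0, 50.0, nbins + 1)
    counts, _ = np.histogram(positions, bins=edges)
    return PositionHistogram(bin_edges=edges, counts=counts, n_dna=int(n_dna))


def _folded_gaussian_cdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    """CDF on [0, 50] of a Gaussian folded at the 50% midline (the two
    DNA ends are indistinguishable, so mass beyond 50 reflects back)."""
    return (norm.cdf(x, mu, sd) + norm.sf(100.0 - x, mu, sd)
            - norm.cdf(0.0, mu, sd) - norm.sf(100.0, mu, sd))


def _position_model(edges: np.ndarray, area: float, mu: float, sd: float,
                    bg: float) -> np.ndarray:
    return bg + area * np.diff(_folded_gaussian_cdf(edges, mu, sd))


def fit_position_model(histogram: PositionHistogram,
                       site_pct: float = 49.8) -> GaussianFitResult:
    """Constant background + one Gaussian centred near the specific site.

    The Gaussian is folded at the 50% midline and its centre is bounded
    within +/-5% of ``site_pct``; the returned area is in event counts.
    """
    counts = histogram.counts.astype(float)
    if counts.sum() == 0:
        return GaussianFitResult(components=((site_pct, 1.5, 0.0),),
                                 background_level=0.0, residual_rss=0.0,
                                 success=True, message="empty histogram")
    edges = histogram.bin_edges
    near = np.abs(histogram.bin_centers - min(site_pct, 49.9)) <= 5.0
    bg0 = float(np.median(counts[~near])) if (~near).any() else 0.0
    a0 = max(float(counts[near].sum() - bg0 * near.sum()), 1.0)
    p0 = [a0, min(site_pct, 49.9), 1.5, max(bg0, 1e-3)]
    lo = [0.0, site_pct - 5.0, 0.3, 0.0]
    hi = [max(3.0 * counts.sum(), 1.0), min(site_pct + 5.0, 50.0), 10.0,
          max(3.0 * counts.max(), 1.0)]
    p0 = np.clip(p0, lo, hi)

    def resid(p):
        return _position_model(edges, *p) - counts

    try:
        res = optimize.least_squares(resid, p0, bounds=(lo, hi),
                                     max_nfev=5000)
    except Exception as exc:  # pragma: no cover - defensive
        return GaussianFitResult(components=(), background_level=np.nan,
                                 residual_rss=np.nan, success=False,
                                 message=str(exc))
    area, mu, sd, bg = res.x
    return GaussianFitResult(components=((float(mu), float(sd), float(area)),),
                             background_level=float(bg),
                             residual_rss=float(np.sum(res.fun ** 2)),
                             success=bool(res.success),
                             message=res.message)


def specificity(A_sp: float, A_nsp: float, N: int = N_SITES_DEFAULT) -> float:
    """S = N * (A_sp / A_nsp) + 1.

    A_sp is the area under the specific-site Gaussian (event counts),
    A_nsp the total nonspecific background area over 0-50% of the DNA
    length, and N the number of available binding sites (base pairs).
    """
    if N < 1:
        raise InvalidConfigError("N must be >= 1")
    if not A_nsp > 0:
        raise ZeroDivisionError(
            "specificity undefined: no nonspecific events observed")
    return float(N * (A_sp / A_nsp) + 1.0)


def specificity_from_fit(fit: GaussianFitResult,
                         histogram: PositionHistogram,
                         N: int = N_SITES_DEFAULT,
                         sd_over_replicates: float | None = None
                         ) -> SpecificityResult:
    """Assemble a specificity estimate from a position-model fit.

    A_nsp is the fitted background level times the number of bins, i.e.
    the total background area in event counts over 0-50% of DNA length.
    """
    if not fit.success or not fit.components:
        raise FitError(f"position fit failed: {fit.message}")
    _mu, _sd, area = fit.components[0]
    A_nsp = fit.background_level * (len(histogram.bin_edges) - 1)
    S = specificity(area, A_nsp, N)
    in_bin = (histogram.bin_centers >= SPECIFIC_BIN[0]) & \
             (histogram.bin_centers <= SPECIFIC_BIN[1])
    occupancy = float(histogram.counts[in_bin].sum() / histogram.n_dna)
    return SpecificityResult(S=S, A_sp=float(area), A_nsp=float(A_nsp), N=N,
                             occupancy_per_dna=occupancy,
                             sd_over_replicates=sd_over_replicates)


def occupancy_at_site(measurements: pd.DataFrame, n_dna,
                      bin_pct: tuple[float, float] = SPECIFIC_BIN,
                      mode: str = "events"):
    """Binding events in the specific bin per DNA, averaged over replicates.

    ``n_dna`` is a mapping replicate -> number of DNA molecules analysed
    (or a single count applied to every replicate).  ``mode`` counts
    events per DNA (default) or molecules with at least one event.
    Returns (mean, sd, per_replicate dict); sd is None for a single
    replicate rather than zero.
    """
    if mode not in ("events", "molecules"):
        raise InvalidConfigError("mode must be 'events' or 'molecules'")
    lo, hi = bin_pct
    reps = sorted(measurements["replicate"].unique()) if len(measurements) \
        else []
    if not reps:
        if np.isscalar(n_dna):
            return 0.0, None, {}
        reps = sorted(n_dna.keys())
    per_rep = {}
    for rep in reps:
        sub = measurements[measurements["replicate"] == rep] \
            if len(measurements) else measurements
        pos = sub["position_pct_folded"].to_numpy(dtype=float) \
            if len(sub) else np.empty(0)
        sel = (pos >= lo) & (pos <= hi)
        count = int(sub.loc[sel, "molecule_id"].nunique()) \
            if mode == "molecules" else int(sel.sum())
        denom = n_dna if np.isscalar(n_dna) else n_dna[rep]
        if denom <= 0:
            raise InvalidConfigError(f"n_dna for replicate {rep!r} must be > 0")
        per_rep[rep] = count / denom
    values = np.array(list(per_rep.values()))
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else None
    return mean, sd, per_rep


def _angle_model(edges: np.ndarray, params: np.ndarray, k: int) -> np.ndarray:
    """Bin contents for k reflected-at-zero Gaussian components + nothing
    else; angles are magnitudes so each component contributes its mirror
    image at negative angles folded back."""
    out = np.zeros(len(edges) - 1)
    for j in range(k):
        area, mu, sd = params[3 * j:3 * j + 3]
        cdf = (norm.cdf(edges, mu, sd) + norm.sf(-edges, mu, sd)
               - norm.cdf(0.0, mu, sd) - norm.sf(0.0, mu, sd))
        out += area * np.diff(cdf)
    return out


def decompose_bend_states(angles, k: int = 3,
                          init_means=(0.0, 35.0, 70.0),
                          init_sd: float = 8.0,
                          bin_width_deg: float = 5.0) -> GaussianFitResult:
    """k-component Gaussian decomposition of a bend-angle histogram.

    Components are reflected at 0 deg (angles are magnitudes, so the 0
    deg straight-DNA state appears as a half-Gaussian); centres are
    bounded to +/-15 deg of their initialisation.  Requires at least 30
    angles.
    """
    angles = np.asarray(angles, dtype=float)
    if k not in (1, 2, 3):
        raise InvalidConfigError("k must be 1, 2 or 3")
    if len(angles) < 30:
        raise SmallSampleError(
            f"need >= 30 angles for a bend-state decomposition, "
            f"got {len(angles)}")
    if np.any(angles < 0) or np.any(angles >= 180):
        raise InvalidConfigError("angles must lie in [0, 180)")
    init_means = tuple(init_means)[:k]
    if len(init_means) < k:
        raise InvalidConfigError("need one init mean per component")
    edges = np.arange(0.0, 180.0 + bin_width_deg, bin_width_deg)
    counts, _ = np.histogram(angles, bins=edges)
    n = float(len(angles))
    p0, lo, hi = [], [], []
    for mu in init_means:
        p0 += [n / k, mu, init_sd]
        if mu == 0.0:
            # the straight-DNA state is a half-Gaussian: centre pinned
            # at 0 (a folded normal with small mu is unidentifiable)
            lo += [0.0, 0.0, 2.0]
            hi += [3.0 * n, 1e-9, 30.0]
        else:
            lo += [0.0, max(mu - 15.0, 0.0), 2.0]
            hi += [3.0 * n, mu + 15.0, 30.0]
    p0 = np.clip(p0, lo, hi)

    def resid(p):
        return _angle_model(edges, p, k) - counts

    res = optimize.least_squares(resid, p0, bounds=(lo, hi), max_nfev=8000)
    comps = tuple(sorted(
        ((float(res.x[3 * j + 1]), float(res.x[3 * j + 2]),
          float(res.x[3 * j])) for j in range(k)),
        key=lambda c: c[0]))
    return GaussianFitResult(components=comps, background_level=0.0,
                             residual_rss=float(np.sum(res.fun ** 2)),
                             success=bool(res.success), message=res.message)


def uniform_background_gof(positions, nbins: int = 10) -> float:
    """Chi-square goodness-of-fit p-value of folded positions against a
    uniform background on [0, 50]."""
    counts, _ = np.histogram(np.asarray(positions, dtype=float),
                             bins=np.linspace(0.0, 50.0, nbins + 1))
    return float(chisquare(counts).pvalue)


def _stars(p: float) -> str:
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_replicates(group_a, group_b) -> ReplicateComparison:
    """Two-tailed pooled-variance t-test between two triplicates (df = 4).

    Zero pooled variance with equal means gives t = 0, p = 1; with
    unequal means the comparison is flagged infinite-t.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) != 3 or len(b) != 3:
        raise InvalidConfigError(
            "replicate comparison expects exactly 3 values per group")
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    scale = max(1e-300, abs(a.mean()), abs(b.mean()))
    if sp2 <= (1e-12 * scale) ** 2:  # zero up to float rounding
        if diff == 0.0:
            return ReplicateComparison(0.0, df, 1.0, "ns")
        return ReplicateComparison(float(np.sign(diff) * np.inf), df, 0.0,
                                   _stars(0.0), infinite_t=True)
    t_stat = diff / np.sqrt(sp2 * (1.0 / len(a) + 1.0 / len(b)))
    p = float(2.0 * t_dist.sf(abs(t_stat), df))
    return ReplicateComparison(float(t_stat), df, p, _stars(p))
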