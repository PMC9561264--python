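"""Hill fits of fluorescence-polarisation titration curves.

Equilibrium binding is summarised by the single-site Hill model

    P(c) = P0 + dP * c^n / (KD^n + c^n)

fit to polarisation versus total ligand concentration; a fit is accepted
only when R^2 >= 0.95, and replicate KDs are averaged arithmetically.
The Hill coefficient n is fitted (bounded to [0.5, 4]) by default but
can be fixed at 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .core import FitError, InvalidConfigError

__all__ = [
    "TitrationCurve",
    "HillFit",
    "hill_model",
    "fit_hill",
    "summarise_affinity",
    "simulate_titration",
]

R2_ACCEPT = 0.95


@dataclass(frozen=True)
class TitrationCurve:
    """One titration: ascending concentrations (nM) and polarisation."""

    concentrations: np.ndarray
    polarisation: np.ndarray
    replicate: str = "r1"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        p = np.asarray(self.polarisation, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "polarisation", p)
        if c.shape != p.shape or c.ndim != 1:
            raise InvalidConfigError("concentration/polarisation mismatch")
        if len(c) < 6:
            raise InvalidConfigError("need at least 6 titration points")
        if np.any(c < 0) or np.any(np.diff(c) <= 0):
            raise InvalidConfigError(
                "concentrations must be >= 0 and strictly increasing")


@dataclass(frozen=True)
class HillFit:
    KD: float          # nM
    hill_n: float
    baseline: float
    amplitude: float
    r_squared: float
    accepted: bool     # R^2 >= 0.95
    reliable: bool     # KD within the titrated range x [0.1, 10]
    replicate: str = ""


def hill_model(c, KD, n, baseline, amplitude):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(c > 0, c ** n / (KD ** n + c ** n), 0.0)
    return baseline + amplitude * frac


def fit_hill(curve: TitrationCurve, fix_n: bool = False) -> HillFit:
    """Least-squares single-Hill fit with data-driven initialisation.

    Start values: baseline = min signal, amplitude = signal range,
    KD = concentration at half-range, n = 1.
    """
    c, p = curve.concentrations, curve.polarisation
    baseline0 = float(p.min())
    amp0 = float(p.max() - p.min())
    if amp0 <= 0:
        raise FitError("titration has no signal range")
    half = baseline0 + 0.5 * amp0
    kd0 = float(np.interp(half, p, c)) if np.all(np.diff(p) >= 0) \
        else float(np.median(c[c > 0]))
    kd0 = max(kd0, float(c[c > 0].min()) if (c > 0).any() else 1.0)
    cmax = float(c.max())
    cmin_pos = float(c[c > 0].min()) if (c > 0).any() else 1e-3

    if fix_n:
        def model(cc, kd, b, a):
            return hill_model(cc, kd, 1.0, b, a)
        p0 = [kd0, baseline0, amp0]
        lo = [1e-6, -np.inf, 0.0]
        hi = [1e3 * cmax, np.inf, np.inf]
    else:
        def model(cc, kd, n, b, a):
            return hill_model(cc, kd, n, b, a)
        p0 = [kd0, 1.0, baseline0, amp0]
        lo = [1e-6, 0.5, -np.inf, 0.0]
        hi = [1e3 * cmax, 4.0, np.inf, np.inf]
    try:
        popt, _ = optimize.curve_fit(model, c, p, p0=p0, bounds=(lo, hi),
                                     maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Hill fit did not converge: {exc}") from exc
    pred = model(c, *popt)
    ss_res = float(np.sum((p - pred) ** 2))
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    kd = float(popt[0])
    n_hill = 1.0 if fix_n else float(popt[1])
    baseline, amplitude = (float(popt[-2]), float(popt[-1]))
    reliable = bool(0.1 * cmin_pos <= kd <= 10.0 * cmax)
    return HillFit(KD=kd, hill_n=n_hill, baseline=baseline,
                   amplitude=amplitude, r_squared=r2,
                   accepted=bool(r2 >= R2_ACCEPT), reliable=reliable,
                   replicate=curve.replicate)


def summarise_affinity(fits) -> tuple[float, float | None, int]:
    """Mean +/- SD of KD over accepted replicate fits.

    Rejected fits (R^2 < 0.95) are excluded; if none are accepted a
    :class:`FitError` is raised.  Returns (mean, sd, n_used); sd is None
    with fewer than two accepted fits.
    """
    used = [f.KD for f in fits if f.accepted]
    if not used:
        raise FitError("no accepted Hill fits (all R^2 < 0.95)")
    used = np.asarray(used)
    sd = float(used.std(ddof=1)) if len(used) > 1 else None
    return float(used.mean()), sd, int(len(used))


def simulate_titration(KD: float, concentrations, rng: np.random.Generator,
                       hill_n: float = 1.0, baseline: float = 50.0,
                       amplitude: float = 150.0,
                       noise_fraction: float = 0.02,
                       replicate: str = "r1") -> TitrationCurve:
    """Synthetic titration with multiplicative Gaussian noise."""
    c = np.asarray(concentrations, dtype=float)
    p = hill_model(c, KD, hill_n, baseline, amplitude)
    if noise_fraction > 0:
        p = p * (1.0 + rng.normal(0.0, noise_fraction, size=p.shape))
    return TitrationCurve(concentrations=c, polarisation=p,
                          replicate=replicate)


def fits_to_frame(fits) -> pd.DataFrame:
    """Per-replicate fit table for CSV output."""
    return pd.DataFrame([{
        "replicate": f.replicate, "KD_nM": f.KD, "hill_n": f.hill_n,
        "baseline": f.baseline, "amplitude": f.amplitude,
        "r_squared": f.r_squared, "accepted": f.accepted,
        "reliable": f.reliable,
    } for f in fits])
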