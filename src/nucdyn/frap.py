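"""FRAP normalization, one-phase-association fitting, and immobile fraction.

The normalized recovery signal corrects for focal-plane and biological
drift with one or two non-photobleached reference regions:

    N(t) = (Ip - b) * Ap / ((Inp - b) * Anp)

where Ip/Ap are the bleached region's mean intensity and area, Inp/Anp the
reference's, and b the background.  Post-bleach recovery is fitted to a
one-phase association

    N(t) = N0 + (plateau - N0) * (1 - exp(-k t))

giving the half-time t50 = ln(2)/k, and the immobile fraction is the gap
between the prebleach level and the fitted plateau (relative to prebleach).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["FrapSeries", "FrapFit", "normalize_frap", "fit_recovery",
           "immobile_fraction", "analyze_frap"]


@dataclass
class FrapSeries:
    """Raw two-region FRAP measurements; bleach at t=0.

    Reference-region fields accept one series or a list of series (one per
    reference region); a single background series is shared.
    """

    times: np.ndarray  # s, negative = prebleach
    Ip: np.ndarray
    Ap: np.ndarray | float
    Inp: np.ndarray | list[np.ndarray]
    Anp: np.ndarray | float | list
    background: np.ndarray | float
    prebleach: np.ndarray  # bool mask of prebleach samples

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.Ip = np.asarray(self.Ip, float)
        self.prebleach = np.asarray(self.prebleach, bool)
        n_post = int((~self.prebleach).sum())
        if n_post < 3:
            raise ValueError("need at least 3 post-bleach samples")

    @property
    def n_references(self) -> int:
        return len(self.Inp) if isinstance(self.Inp, list) else 1


@dataclass
class FrapFit:
    """One-phase-association fit results."""

    plateau: float
    k: float  # 1/s
    n0: float
    residual_norm: float
    prebleach_level: float
    flags: list[str] = field(default_factory=list)

    @property
    def t_half(self) -> float:
        return math.log(2) / self.k

    @property
    def immobile_fraction(self) -> float:
        return immobile_fraction(self.prebleach_level, self.plateau)


def _ref_product(inp, anp, b):
    """Background-subtracted, area-weighted reference intensity."""
    if isinstance(inp, list):
        anps = anp if isinstance(anp, list) else [anp] * len(inp)
        terms = [(np.asarray(i, float) - b) * a for i, a in zip(inp, anps)]
        return np.mean(terms, axis=0)
    return (np.asarray(inp, float) - b) * anp


def normalize_frap(series: FrapSeries) -> tuple[np.ndarray, np.ndarray]:
    """Two-region drift-corrected normalization.

    Returns ``(N, ok)`` where ``N[t] = (Ip-b)*Ap / ((Inp-b)*Anp)`` and
    ``ok`` flags time points with a positive reference denominator; points
    where the background reaches the reference are rejected (N set to NaN)
    rather than silently kept.  With two reference regions their
    background-subtracted area-weighted intensities are averaged before
    division.  N is invariant to a common gain on all intensities.
    """
    b = np.asarray(series.background, float)
    denom = _ref_product(series.Inp, series.Anp, b)
    ok = denom > 0
    n = np.full_like(series.Ip, np.nan, dtype=float)
    n[ok] = (series.Ip[ok] - np.broadcast_to(b, series.Ip.shape)[ok]) \
        * np.broadcast_to(np.asarray(series.Ap, float), series.Ip.shape)[ok] / denom[ok]
    return n, ok


def fit_recovery(times: np.ndarray, n_values: np.ndarray,
                 rescale_prebleach: bool = False,
                 prebleach_level: float | None = None) -> FrapFit:
    """Fit the post-bleach recovery to a one-phase association.

    ``times`` and ``n_values`` must be post-bleach samples only, with the
    bleach at t=0; the bleach-frame acquisition itself (t == 0) is excluded
    from the fit.  Initialization: plateau from the last-quartile mean, k
    from the time to half-plateau, N0 from the first sample.  Set
    ``rescale_prebleach`` to divide the curve by ``prebleach_level`` before
    fitting (both conventions are reported via ``prebleach_level``).
    """
    t = np.asarray(times, float)
    n = np.asarray(n_values, float)
    keep = np.isfinite(n) & (t >= 0)
    t, n = t[keep], n[keep]
    if t.size < 3:
        raise ValueError("need at least 3 finite post-bleach samples")
    flags = []
    pre = 1.0 if prebleach_level is None else float(prebleach_level)
    if rescale_prebleach:
        if pre <= 0:
            raise ValueError("prebleach_level must be positive to rescale")
        n = n / pre
        pre_for_fit = 1.0
    else:
        pre_for_fit = pre
    fit_mask = t > 0  # drop the bleach-frame acquisition
    if fit_mask.sum() < 3:
        fit_mask = np.ones_like(t, bool)
        flags.append("bleach_frame_included")
    tf, nf = t[fit_mask], n[fit_mask]

    def model(tt, n0, plateau, k):
        return n0 + (plateau - n0) * (1.0 - np.exp(-k * tt))

    q3 = np.quantile(tf, 0.75)
    plateau0 = float(nf[tf >= q3].mean())
    n0_0 = float(n[0])
    half_level = n0_0 + 0.5 * (plateau0 - n0_0)
    above = np.flatnonzero(nf >= half_level) if plateau0 > n0_0 else np.array([])
    t_half0 = float(tf[above[0]]) if above.size else float(tf[-1] / 4)
    k0 = math.log(2) / max(t_half0, tf[0] if tf[0] > 0 else np.diff(tf).mean())
    try:
        popt, _ = curve_fit(
            model, tf, nf, p0=[n0_0, plateau0, k0],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"one-phase association fit did not converge (p0={[n0_0, plateau0, k0]}): {err}"
        ) from err
    n0, plateau, k = (float(v) for v in popt)
    resid = float(np.linalg.norm(model(tf, *popt) - nf))
    return FrapFit(plateau=plateau, k=k, n0=n0, residual_norm=resid,
                   prebleach_level=pre_for_fit, flags=flags)


def immobile_fraction(prebleach_n: float, plateau: float) -> float:
    """Fraction of the prebleach signal that never recovers.

    ``(prebleach - plateau) / prebleach``, which reduces to the plain
    subtraction when the prebleach level is normalized to 1.  Values
    outside [0, 1] (overshoot) are returned as-is so callers can flag them.
    """
    if prebleach_n <= 0:
        raise ValueError("prebleach level must be positive")
    return (prebleach_n - plateau) / prebleach_n


def analyze_frap(series: FrapSeries, rescale_prebleach: bool = False) -> dict:
    """Normalize, fit, and summarize one FRAP experiment."""
    n, ok = normalize_frap(series)
    pre_mask = series.prebleach & ok
    pre_level = float(n[pre_mask].mean()) if pre_mask.any() else 1.0
    post = ~series.prebleach
    fit = fit_recovery(series.times[post], n[post],
                       rescale_prebleach=rescale_prebleach,
                       prebleach_level=pre_level)
    return {
        "normalized": n,
        "ok": ok,
        "fit": fit,
        "plateau": fit.plateau,
        "k": fit.k,
        "t_half": fit.t_half,
        "immobile_fraction": fit.immobile_fraction,
        "prebleach_level": pre_level,
        "n_references": series.n_references,
    }
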