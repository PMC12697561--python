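"""Nuclear kinematics: velocities, rolling-window MSD, and active motion.

Apical-basal velocities are computed over 1-min windows, and periods of
active (directed) motion are detected with a rolling-window time-averaged
mean-squared-displacement analysis: within each window of ``W`` points the
MSD follows a power law ``MSD(tau) ~ tau**gamma``; ``gamma`` is the
ordinary-least-squares slope of log MSD versus log lag over integer lags
``4 .. floor(3*(W-1)/4)`` (the first three lags are excluded to avoid
short-timescale artifacts), and a window is *active* when ``gamma > 1``.
Trajectories are denoised with a fifth-order median filter beforehand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Trajectory",
    "MsdWindowConfig",
    "MsdWindowResult",
    "median_prefilter",
    "ab_velocity",
    "rolling_msd",
    "fit_gamma",
    "classify_active",
    "active_intervals",
    "percent_active",
    "speed_summary",
    "analyze_trajectory",
]


@dataclass
class Trajectory:
    """Uniformly sampled positions of one tracked nucleus.

    ``positions`` is ``(n,)`` for depth-only data or ``(n, d)``; units um.
    ``dt`` is the sampling interval in seconds.
    """

    track_id: int
    positions: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        if self.positions.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]


@dataclass
class MsdWindowConfig:
    """Rolling-window MSD settings.

    ``window`` (W) is the odd number of points per window; the fitted lag
    range is the single rule ``tau in [4, floor(3*(W-1)/4)]`` (which
    already excludes lags 1-3), so W >= 7 is required for a non-empty
    range.  The default W=15 spans ~4-5 min at 15-20 s sampling and gives
    lags 4..10.
    """

    window: int = 15
    median_filter_order: int = 5
    # Consecutive gamma>1 windows required per active interval.  Adjacent
    # rolling windows share W-1 points, so their gamma estimates are heavily
    # correlated and single noise excursions persist across many windows;
    # requiring ~W-ish consecutive active windows (about one window span,
    # ~3 min at 15-s sampling) keeps stationary confined tracks from being
    # called active while directed runs light up far longer stretches.
    min_run: int = 12

    lag_min: int = field(init=False, default=4)

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 7:
            raise ValueError("window must be odd and >= 7")
        if self.median_filter_order % 2 == 0:
            raise ValueError("median filter order must be odd")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")

    @property
    def lag_max(self) -> int:
        return math.floor(3 * (self.window - 1) / 4)


@dataclass
class MsdWindowResult:
    """One rolling window: its MSD curve, fitted exponent, and active flag."""

    center_index: int
    msd: np.ndarray  # msd[k] is MSD at lag k+1 frames, um^2
    gamma: float
    r_squared: float

    @property
    def active(self) -> bool:
        return np.isfinite(self.gamma) and self.gamma > 1.0


def median_prefilter(traj: Trajectory, order: int = 5) -> Trajectory:
    """Sliding-median denoising per coordinate, edges padded by repetition.

    Trajectories shorter than the filter order are returned unfiltered
    with a warning.
    """
    if order % 2 == 0:
        raise ValueError("order must be odd")
    if traj.n_points < order:
        warnings.warn(
            f"trajectory {traj.track_id} shorter than the median filter order; left unfiltered",
            stacklevel=2,
        )
        return traj
    p = traj.positions
    if p.ndim == 1:
        filt = ndimage.median_filter(p, size=order, mode="nearest")
    else:
        filt = np.column_stack(
            [ndimage.median_filter(p[:, j], size=order, mode="nearest") for j in range(p.shape[1])]
        )
    return Trajectory(traj.track_id, filt, traj.dt)


def ab_velocity(traj: Trajectory, window_s: float = 60.0) -> np.ndarray:
    """Apical-basal velocity (um/min) over a sliding 1-min window.

    For depth series ``z`` the velocity assigned to each window is the
    displacement across the window divided by its duration; a track of
    duration shorter than the window yields an empty series.  Speeds are
    ``abs`` of the returned values.
    """
    z = traj.positions if traj.positions.ndim == 1 else traj.positions[:, 0]
    k = int(round(window_s / traj.dt))
    if k < 1:
        raise ValueError("window shorter than the sampling interval")
    if traj.n_points <= k:
        return np.zeros(0)
    disp = z[k:] - z[:-k]
    return disp / (k * traj.dt) * 60.0


def rolling_msd(traj: Trajectory, config: MsdWindowConfig | None = None) -> list[MsdWindowResult]:
    """Time-averaged MSD in every window of W consecutive points.

    ``MSD(tau)`` averages the squared displacement over all overlapping
    pairs at lag ``tau`` inside the window, for ``tau = 1..W-1``; the
    power-law exponent is then fitted per window (NaN where the fit is
    undefined).  Requires ``n_points >= W``.
    """
    config = config or MsdWindowConfig()
    w = config.window
    if traj.n_points < w:
        return []
    p = traj.positions
    if p.ndim == 1:
        p = p[:, None]
    results = []
    half = (w - 1) // 2
    for start in range(traj.n_points - w + 1):
        seg = p[start : start + w]
        msd = np.empty(w - 1)
        for tau in range(1, w):
            d = seg[tau:] - seg[:-tau]
            msd[tau - 1] = np.mean(np.sum(d * d, axis=1))
        gamma, r2 = fit_gamma(msd, config)
        results.append(MsdWindowResult(start + half, msd, gamma, r2))
    return results


def fit_gamma(msd: np.ndarray, config: MsdWindowConfig | None = None) -> tuple[float, float]:
    """Power-law exponent of an MSD curve by log-log least squares.

    ``msd[k]`` is the MSD at lag ``k+1`` frames.  The slope of
    ``log MSD`` versus ``log tau`` is fitted (unweighted OLS) over integer
    lags ``[4, floor(3*(W-1)/4)]``.  Returns ``(gamma, r_squared)``;
    ``(nan, nan)`` when any MSD in the lag range is non-positive.
    """
    config = config or MsdWindowConfig()
    lags = np.arange(config.lag_min, config.lag_max + 1)
    if lags.size < 2 or msd.shape[0] < config.lag_max:
        return float("nan"), float("nan")
    y = np.asarray(msd, float)[lags - 1]
    if np.any(y <= 0) or not np.all(np.isfinite(y)):
        return float("nan"), float("nan")
    lx, ly = np.log(lags.astype(float)), np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    fit = slope * lx + intercept
    ss_res = float(np.sum((ly - fit) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def active_intervals(gammas: np.ndarray, min_run: int = 12) -> list[tuple[int, int]]:
    """Maximal runs of >= min_run consecutive active (gamma > 1) windows.

    Returned as half-open ``(start, stop)`` window-index intervals.
    """
    g = np.asarray(gammas, float)
    active = np.isfinite(g) & (g > 1.0)
    intervals = []
    start = None
    for i, a in enumerate(active):
        if a and start is None:
            start = i
        elif not a and start is not None:
            if i - start >= min_run:
                intervals.append((start, i))
            start = None
    if start is not None and len(active) - start >= min_run:
        intervals.append((start, len(active)))
    return intervals


def classify_active(gammas: np.ndarray, min_run: int = 12) -> bool:
    """A nucleus is active iff it has at least one active interval."""
    return len(active_intervals(gammas, min_run)) > 0


def percent_active(gamma_series: list[np.ndarray], min_run: int = 12) -> float:
    """Percent of analyzable nuclei with at least one active interval.

    Nuclei with no defined gamma in any window are excluded from the
    denominator.  Returns NaN when no nucleus is analyzable.
    """
    n_active = 0
    n_total = 0
    for g in gamma_series:
        g = np.asarray(g, float)
        if g.size == 0 or not np.any(np.isfinite(g)):
            continue
        n_total += 1
        if classify_active(g, min_run):
            n_active += 1
    if n_total == 0:
        return float("nan")
    return 100.0 * n_active / n_total


def speed_summary(traj: Trajectory, window_s: float = 60.0) -> dict[str, float]:
    """Mean and peak 1-min-window apical-basal speed of one track (um/min)."""
    speeds = np.abs(ab_velocity(traj, window_s))
    if speeds.size == 0:
        return {"mean_speed": float("nan"), "peak_speed": float("nan")}
    return {"mean_speed": float(speeds.mean()), "peak_speed": float(speeds.max())}


def analyze_trajectory(traj: Trajectory, config: MsdWindowConfig | None = None,
                       prefilter: bool = True) -> dict:
    """Median-filter, rolling-MSD, and classify one trajectory."""
    config = config or MsdWindowConfig()
    t = median_prefilter(traj, config.median_filter_order) if prefilter else traj
    windows = rolling_msd(t, config)
    gammas = np.array([w.gamma for w in windows])
    return {
        "track_id": traj.track_id,
        "windows": windows,
        "gammas": gammas,
        "intervals": active_intervals(gammas, config.min_run),
        "active": classify_active(gammas, config.min_run),
        **speed_summary(t),
    }
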