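"""Fluorescence ROI quantitation.

Operators for the ROI geometries used in epithelial microtubule/nucleus
imaging: centrosomal disks (2.02 um diameter), perinuclear freehand rings
(3-px stroke), apical rectangles (1x5 um), 3-px-wide line scans, the
gamma-tubulin concentric-disk (15/25 px at 0.168 um/px) local-background
correction, exponential photobleaching correction, t0-baseline
normalization, and ROUT-style robust outlier removal.

Pixel membership is by center inclusion: a pixel belongs to an ROI iff its
center (at ``index + 0.5``) satisfies the ROI geometry.  This keeps every
mean exactly reproducible by brute-force pixel enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "DiskRoi", "RectRoi", "RingRoi", "LineRoi",
    "roi_mask", "roi_mean", "integrated_density",
    "background_subtract_normalize", "annulus_corrected_mean",
    "bleach_correct", "line_scan", "remove_outliers_rout",
    "GAMMA_TUB_PIXEL_SIZE_UM",
]

GAMMA_TUB_PIXEL_SIZE_UM = 0.168  # calibration at which the 15/25 px disks are defined


def _pixel_centers(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return yy + 0.5, xx + 0.5


@dataclass
class DiskRoi:
    """Disk ROI: center (y, x) and diameter, in pixels."""
    center: tuple[float, float]
    diameter: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        cy, cx = _pixel_centers(shape)
        return (cy - self.center[0]) ** 2 + (cx - self.center[1]) ** 2 <= (self.diameter / 2) ** 2


@dataclass
class RectRoi:
    """Axis-aligned rectangle: corner (y, x) and extent (h, w), pixels."""
    corner: tuple[float, float]
    extent: tuple[float, float]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        cy, cx = _pixel_centers(shape)
        y0, x0 = self.corner
        h, w = self.extent
        return (cy >= y0) & (cy < y0 + h) & (cx >= x0) & (cx < x0 + w)


def _dist_to_segments(py: np.ndarray, px: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Distance from each (py,px) point to the nearest polyline segment."""
    d = np.full(py.shape, np.inf)
    for (y0, x0), (y1, x1) in zip(pts[:-1], pts[1:]):
        vy, vx = y1 - y0, x1 - x0
        L2 = vy * vy + vx * vx
        if L2 == 0:
            dd = np.hypot(py - y0, px - x0)
        else:
            t = np.clip(((py - y0) * vy + (px - x0) * vx) / L2, 0.0, 1.0)
            dd = np.hypot(py - (y0 + t * vy), px - (x0 + t * vx))
        d = np.minimum(d, dd)
    return d


@dataclass
class RingRoi:
    """Stroked closed contour (freehand ring): vertices (n,2) in (y,x) px.

    The mask contains pixels whose center lies within ``width/2`` of the
    closed polyline, emulating a freehand 3-px-thick outline.
    """
    contour: np.ndarray
    width: float = 3.0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        pts = np.asarray(self.contour, float)
        if not np.allclose(pts[0], pts[-1]):
            pts = np.vstack([pts, pts[0]])  # close the contour
        cy, cx = _pixel_centers(shape)
        return _dist_to_segments(cy, cx, pts) <= self.width / 2.0


@dataclass
class LineRoi:
    """Open line segment with a stroke width, pixels."""
    start: tuple[float, float]
    end: tuple[float, float]
    width: float = 3.0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        cy, cx = _pixel_centers(shape)
        pts = np.array([self.start, self.end], float)
        return _dist_to_segments(cy, cx, pts) <= self.width / 2.0


Roi = DiskRoi | RectRoi | RingRoi | LineRoi


def roi_mask(image: np.ndarray, roi: Roi) -> np.ndarray:
    mask = roi.mask(image.shape)
    if not mask.any():
        raise ValueError(f"ROI covers no pixels: {roi}")
    return mask


def roi_mean(image: np.ndarray, roi: Roi) -> float:
    """Mean intensity over the pixels whose centers fall inside the ROI."""
    return float(image[roi_mask(image, roi)].mean())


def integrated_density(image: np.ndarray, roi: Roi) -> tuple[float, int]:
    """ROI pixel sum (mean x area) and pixel count."""
    mask = roi_mask(image, roi)
    return float(image[mask].sum()), int(mask.sum())


def background_subtract_normalize(
    means: np.ndarray, backgrounds: np.ndarray | float,
    baseline_mean_t0: float, baseline_background_t0: float | None = None,
) -> np.ndarray:
    """Background-subtract a mean-intensity series and normalize to t0.

    ``(mean - background) / (baseline_mean_t0 - baseline_background_t0)``;
    the baseline is the population-average mean at time 0, so the t0
    population mean of the normalized values is 1 by construction.
    """
    means = np.asarray(means, float)
    bg = np.broadcast_to(np.asarray(backgrounds, float), means.shape)
    base_bg = bg.flat[0] if baseline_background_t0 is None else baseline_background_t0
    denom = baseline_mean_t0 - base_bg
    if denom <= 0:
        raise ValueError("baseline must exceed its background")
    return (means - bg) / denom


def annulus_corrected_mean(image: np.ndarray, center: tuple[float, float],
                           d_small: float = 15.0, d_large: float = 25.0,
                           pixel_size_um: float = GAMMA_TUB_PIXEL_SIZE_UM) -> float:
    """Local-background-corrected spot mean via concentric disks.

    Integrated densities of a small and a large concentric disk are
    measured; their difference over the annulus area gives the local
    background mean, which is subtracted from the small disk's mean.  The
    default diameters are 15 and 25 px at 0.168 um/px and are rescaled
    when the image calibration differs.
    """
    scale = GAMMA_TUB_PIXEL_SIZE_UM / pixel_size_um
    ds, dl = d_small * scale, d_large * scale
    if dl <= ds:
        raise ValueError("large diameter must exceed the small diameter")
    id_s, a_s = integrated_density(image, DiskRoi(center, ds))
    id_l, a_l = integrated_density(image, DiskRoi(center, dl))
    if a_l <= a_s:
        raise ValueError("annulus covers no pixels")
    local_bg = (id_l - id_s) / (a_l - a_s)
    return id_s / a_s - local_bg


def bleach_correct(frames: np.ndarray, times: np.ndarray | None = None
                   ) -> tuple[np.ndarray, dict]:
    """Exponential-fit photobleaching correction of a time-lapse.

    Fits the frame means to ``a * exp(-b t) + c`` and divides each frame
    by ``fit(t) / fit(0)``, leaving the first frame unchanged.  Falls back
    to simple ratio correction (frame mean / first frame mean) when the
    exponential fit fails, flagged in the returned info dict.
    """
    frames = np.asarray(frames, float)
    if frames.shape[0] < 5:
        raise ValueError("need at least 5 frames to fit a bleach curve")
    t = np.arange(frames.shape[0], dtype=float) if times is None else np.asarray(times, float)
    means = frames.reshape(frames.shape[0], -1).mean(axis=1)

    def model(tt, a, b, c):
        return a * np.exp(-b * tt) + c

    a0 = max(means[0] - means[-1], 1e-12)
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    p0 = [a0, 1.0 / span, float(means[-1])]
    info: dict = {"method": "exponential"}
    try:
        with warnings.catch_warnings():
            # a flat series makes the covariance singular; the fit is still fine
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(model, t, means, p0=p0, maxfev=20000)
        fit = model(t, *popt)
        if np.any(fit <= 0):
            raise RuntimeError("non-positive fitted bleach curve")
        ratio = fit / fit[0]
        info["params"] = {"a": popt[0], "b": popt[1], "c": popt[2]}
    except RuntimeError:
        ratio = means / means[0]
        info = {"method": "ratio", "flag": "exponential_fit_failed"}
    corrected = frames / ratio[(slice(None),) + (None,) * (frames.ndim - 1)]
    return corrected, info


def line_scan(image: np.ndarray, start: tuple[float, float], end: tuple[float, float],
              width: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity profile along a line with a perpendicular stroke.

    Samples at pixel pitch along the segment; at each position the mean is
    taken across ``width`` bilinear samples spaced 1 px along the normal
    (3-px stroke by default).  Returns ``(distance_px, profile)``.
    """
    p0 = np.asarray(start, float)
    p1 = np.asarray(end, float)
    length = float(np.linalg.norm(p1 - p0))
    n = max(2, int(round(length)) + 1)
    ts = np.linspace(0.0, 1.0, n)
    direction = (p1 - p0) / length
    normal = np.array([-direction[1], direction[0]])
    offsets = np.arange(width) - (width - 1) / 2.0
    profiles = []
    for off in offsets:
        pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :] + off * normal[None, :]
        # bilinear sampling on the pixel-center grid
        coords = (pts - 0.5).T
        profiles.append(ndimage.map_coordinates(image.astype(float), coords, order=1, mode="nearest"))
    return ts * length, np.mean(profiles, axis=0)


def remove_outliers_rout(values: np.ndarray, q: float = 0.01
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Robust outlier removal in the spirit of the ROUT test (FDR rate Q).

    For a univariate sample the robust (constant) model is the median with
    scale taken as the robust standard deviation of the residuals (the
    68.27th percentile of their absolute values, small-sample corrected).
    Residual t-scores get two-sided p-values (df = n - 1) and outliers are
    the points rejected by a Benjamini-Hochberg step at rate Q.  Samples
    smaller than 10 are returned untouched.  Returns ``(kept_values,
    outlier_mask)``; removed points are reported, never silently dropped.
    """
    x = np.asarray(values, float)
    n = x.size
    outlier = np.zeros(n, bool)
    if n < 10:
        return x, outlier
    resid = x - np.median(x)
    # robust SD of residuals; n/(n-1) corrects for the fitted location
    rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - 1)
    if rsdr == 0:
        outlier = resid != 0
        return x[~outlier], outlier
    tval = np.abs(resid) / rsdr
    pvals = 2.0 * stats.t.sf(tval, df=n - 1)
    order = np.argsort(pvals)
    thresh = q * (np.arange(1, n + 1)) / n
    passed = pvals[order] <= thresh
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    outlier[order[:k]] = True
    return x[~outlier], outlier
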