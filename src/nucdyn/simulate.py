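"""Synthetic fluorescence time-lapse scenes with ground truth.

Emulates a columnar epithelium (~30-35 um deep) whose ellipsoidal nuclei
start in a common apical plane and disperse basally through a mixture of
active (ballistic run/pause), diffusive, and confined motion.  Every scene
carries its generative parameters and exact trajectories so downstream
stages (segmentation, tracking, midplane metrics, MSD classification, FRAP
fitting, ROI quantitation) can be validated against known truth.

Depth ``z`` is measured positive basally from the apical surface at z=0;
nuclei reflect off the apical boundary rather than crossing it, so apical
exclusion-zone invasion remains simulable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import LabelVolume, VolumeSeries, voxel_centers

__all__ = [
    "SceneConfig",
    "SyntheticTruth",
    "FrapTruthConfig",
    "generate_trajectories",
    "render_volume",
    "generate_frap",
    "generate_roi_fixture",
    "add_localization_noise",
]

MOTION_CLASSES = ("active", "diffusive", "confined")


@dataclass
class SceneConfig:
    """Generative parameters of one synthetic epithelium scene.

    Defaults describe a germband-extension-stage columnar epithelium:
    ~32 um deep cells, nuclei a few micrometers across, spinning-disk-like
    anisotropic voxels (fine xy, ~1 um z), and nuclear speeds on the scale
    of ~0.4-0.5 um/min for actively transported nuclei.
    """

    grid_shape: tuple[int, int, int] = (32, 96, 96)  # (nz, ny, nx) voxels
    voxel_size: tuple[float, float, float] = (1.0, 0.4, 0.4)  # (dz, dy, dx) um
    frame_interval: float = 15.0  # s
    n_frames: int = 20
    n_nuclei: int = 12
    cell_height: float = 32.0  # um, apical surface at 0
    nucleus_radii: tuple[float, float, float] = (2.6, 2.2, 2.2)  # (rz, ry, rx) um
    initial_apical_depth: float = 5.0  # um below apical surface at t=0
    depth_spread: float = 0.0  # um; uniform jitter of initial depth
    motion_mix: dict[str, float] = field(
        default_factory=lambda: {"active": 0.5, "diffusive": 0.25, "confined": 0.25}
    )
    run_speed: float = 0.5  # um/min, basal drive of active nuclei
    run_duration_s: float = 120.0  # mean dwell in the running state
    pause_duration_s: float = 30.0  # mean dwell paused; 0 disables pausing
    diffusion_coeff: float = 0.1  # um^2/min, per-axis Brownian coefficient
    confinement_radius: float = 0.5  # um, hard bound of confined excursion
    confinement_tau_s: float = 20.0  # mean-reversion time of confined walk
    intensity: float = 100.0  # nuclear signal amplitude over 0 background
    gaussian_sd: float = 10.0  # additive read-noise SD
    poisson_scale: float = 0.0  # photons per intensity unit; 0 disables
    psf_sigma: tuple[float, float, float] = (0.5, 0.3, 0.3)  # um per (z,y,x)
    bleach_rate: float = 0.0  # 1/s
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.motion_mix.values()) - 1.0) > 1e-9:
            raise ValueError(f"motion_mix fractions must sum to 1, got {self.motion_mix}")
        if any(k not in MOTION_CLASSES for k in self.motion_mix):
            raise ValueError(f"motion_mix keys must be among {MOTION_CLASSES}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in ("cell_height", "frame_interval", "intensity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(r <= 0 for r in self.nucleus_radii) or any(v <= 0 for v in self.voxel_size):
            raise ValueError("radii and voxel sizes must be positive")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * d for n, d in zip(self.grid_shape, self.voxel_size))


@dataclass
class SyntheticTruth:
    """Ground truth for one scene: trajectories, classes, and metadata.

    ``positions`` has shape ``(n_nuclei, n_frames, 3)`` in (z, y, x) um with
    z measured downward from the apical surface.  Labels in rendered volumes
    are ``index + 1`` and constant over time.
    """

    positions: np.ndarray
    motion_class: list[str]
    config: SceneConfig
    overlap_pairs: list[tuple[int, int, int]] = field(default_factory=list)  # (t, id_a, id_b)

    @property
    def n_nuclei(self) -> int:
        return self.positions.shape[0]

    def label_of(self, index: int) -> int:
        return index + 1

    def to_table(self) -> pd.DataFrame:
        """One row per nucleus per frame: id, t (s), x, y, z (um), class."""
        rows = []
        dt = self.config.frame_interval
        for i in range(self.n_nuclei):
            for t in range(self.positions.shape[1]):
                z, y, x = self.positions[i, t]
                rows.append(
                    {
                        "id": self.label_of(i),
                        "t_s": t * dt,
                        "x_um": x,
                        "y_um": y,
                        "z_um": z,
                        "motion_class": self.motion_class[i],
                    }
                )
        return pd.DataFrame(rows)


def _initial_positions(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Place nuclei on a jittered lateral grid, none clipping the boundary."""
    _, ly, lx = config.extent_um
    rz, ry, rx = config.nucleus_radii
    n = config.n_nuclei
    if n == 0:
        return np.zeros((0, 3))
    n_cols = math.ceil(math.sqrt(n))
    n_rows = math.ceil(n / n_cols)
    margin_y, margin_x = ry + 1.0, rx + 1.0
    ys = np.linspace(margin_y, ly - margin_y, n_rows)
    xs = np.linspace(margin_x, lx - margin_x, n_cols)
    if n_rows > 1 and (ys[1] - ys[0]) < 2.2 * ry:
        raise ValueError("grid too small: nuclei would clip or crowd the lateral boundary")
    if n_cols > 1 and (xs[1] - xs[0]) < 2.2 * rx:
        raise ValueError("grid too small: nuclei would clip or crowd the lateral boundary")
    pos = np.zeros((n, 3))
    depths = config.initial_apical_depth + config.depth_spread * rng.random(n)
    k = 0
    for yy in ys:
        for xx in xs:
            if k >= n:
                break
            jitter = rng.uniform(-0.4, 0.4, size=2)
            pos[k] = (depths[k], yy + jitter[0], xx + jitter[1])
            k += 1
    return pos


def _reflect(value: float, lo: float, hi: float) -> float:
    """Reflect a coordinate back into [lo, hi]."""
    if hi <= lo:
        return lo
    span = hi - lo
    v = (value - lo) % (2 * span)
    return lo + (span - abs(v - span))


def generate_trajectories(config: SceneConfig) -> SyntheticTruth:
    """Simulate one trajectory per nucleus under its assigned motion class.

    Active nuclei alternate constant-velocity basal runs (``run_speed``)
    with pauses; exponential dwell times with the configured means, and
    ``pause_duration_s = 0`` yields uninterrupted ballistic motion.
    Diffusive nuclei follow an isotropic Gaussian random walk with per-axis
    coefficient ``diffusion_coeff``.  Confined nuclei follow a discretized
    mean-reverting (Ornstein-Uhlenbeck) walk hard-bounded at
    ``confinement_radius`` from their anchor.  z reflects at 0 and at
    ``cell_height``.  Identical seeds give identical output.
    """
    rng = np.random.default_rng(config.rng_seed)
    n, nt, dt = config.n_nuclei, config.n_frames, config.frame_interval

    classes: list[str] = []
    counts = {c: int(round(config.motion_mix.get(c, 0.0) * n)) for c in MOTION_CLASSES}
    while sum(counts.values()) < n:
        counts["active"] += 1
    while sum(counts.values()) > n:
        biggest = max(counts, key=counts.get)
        counts[biggest] -= 1
    for c in MOTION_CLASSES:
        classes.extend([c] * counts[c])

    pos = np.zeros((n, nt, 3))
    pos[:, 0, :] = _initial_positions(config, rng)

    step_run = config.run_speed * dt / 60.0  # um per frame while running
    sigma_diff = math.sqrt(2.0 * config.diffusion_coeff * dt / 60.0)  # per axis
    tau = config.confinement_tau_s
    # stationary SD = confinement_radius / 2 so the hard bound is ~2 sigma
    sigma_conf_stat = config.confinement_radius / 2.0
    d_conf = sigma_conf_stat**2 / tau if tau > 0 else 0.0
    sigma_conf = math.sqrt(2.0 * d_conf * dt)

    for i in range(n):
        cls = classes[i]
        p = pos[i, 0].copy()
        if cls == "active":
            running = True
            dwell = rng.exponential(config.run_duration_s) if config.pause_duration_s > 0 else math.inf
            for t in range(1, nt):
                if config.pause_duration_s > 0:
                    dwell -= dt
                    if dwell <= 0:
                        running = not running
                        mean = config.run_duration_s if running else config.pause_duration_s
                        dwell = rng.exponential(mean)
                if running:
                    p[0] += step_run
                p[0] = _reflect(p[0], 0.0, config.cell_height)
                pos[i, t] = p
        elif cls == "diffusive":
            for t in range(1, nt):
                p = p + rng.normal(0.0, sigma_diff, size=3)
                p[0] = _reflect(p[0], 0.0, config.cell_height)
                pos[i, t] = p
        else:  # confined
            anchor = p.copy()
            for t in range(1, nt):
                drift = -(dt / tau) * (p - anchor) if tau > 0 else 0.0
                p = p + drift + rng.normal(0.0, sigma_conf, size=3)
                d = p - anchor
                r = np.linalg.norm(d)
                if r > config.confinement_radius:
                    p = anchor + d * (config.confinement_radius / r)
                p[0] = _reflect(p[0], 0.0, config.cell_height)
                pos[i, t] = p

    return SyntheticTruth(positions=pos, motion_class=classes, config=config)


def add_localization_noise(
    positions: np.ndarray, sd: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Add Gaussian localization error (um) to a truth position array."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return positions + rng.normal(0.0, sd, size=np.shape(positions))


def _rasterize_frame(
    centers: np.ndarray, radii: tuple[float, float, float], config: SceneConfig
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Paint ellipsoids (voxel-center inclusion) into label and signal grids."""
    nz, ny, nx = config.grid_shape
    dz, dy, dx = config.voxel_size
    labels = np.zeros((nz, ny, nx), dtype=np.uint16)
    signal = np.zeros((nz, ny, nx), dtype=np.float64)
    zc, yc, xc = (voxel_centers(nz, dz), voxel_centers(ny, dy), voxel_centers(nx, dx))
    rz, ry, rx = radii
    overlaps: list[tuple[int, int]] = []
    for i, (cz, cy, cx) in enumerate(centers):
        label = i + 1
        iz = np.flatnonzero(np.abs(zc - cz) <= rz)
        iy = np.flatnonzero(np.abs(yc - cy) <= ry)
        ix = np.flatnonzero(np.abs(xc - cx) <= rx)
        if iz.size == 0 or iy.size == 0 or ix.size == 0:
            continue
        sub = np.ix_(iz, iy, ix)
        ez = ((zc[iz] - cz) / rz)[:, None, None] ** 2
        ey = ((yc[iy] - cy) / ry)[None, :, None] ** 2
        ex = ((xc[ix] - cx) / rx)[None, None, :] ** 2
        inside = ez + ey + ex <= 1.0
        prev = labels[sub][inside]
        clashing = np.unique(prev[prev > 0])
        overlaps.extend((int(c), label) for c in clashing)
        block_l = labels[sub]
        block_l[inside] = label
        labels[sub] = block_l
        block_s = signal[sub]
        block_s[inside] = config.intensity
        signal[sub] = block_s
    return labels, signal, overlaps


def render_volume(truth: SyntheticTruth, config: SceneConfig | None = None) -> tuple[VolumeSeries, LabelVolume]:
    """Render a scene: rasterize, PSF-blur, bleach, and add noise.

    Returns the noisy intensity series and the paired ground-truth label
    series (no blur, no noise).  Nuclei overlapping in a frame are recorded
    in ``truth.overlap_pairs`` as ``(frame, label_a, label_b)``.
    """
    config = config or truth.config
    nt = truth.positions.shape[1]
    nz, ny, nx = config.grid_shape
    data = np.zeros((nt, nz, ny, nx), dtype=np.float64)
    labels = np.zeros((nt, nz, ny, nx), dtype=np.uint16)
    sigma_vox = tuple(s / d for s, d in zip(config.psf_sigma, config.voxel_size))
    rng = np.random.default_rng(config.rng_seed + 1)  # independent of trajectory noise
    truth.overlap_pairs = []
    for t in range(nt):
        lab, sig, ovl = _rasterize_frame(truth.positions[:, t, :], config.nucleus_radii, config)
        truth.overlap_pairs.extend((t, a, b) for a, b in ovl)
        labels[t] = lab
        if any(s > 0 for s in sigma_vox):
            sig = ndimage.gaussian_filter(sig, sigma=sigma_vox)
        if config.bleach_rate > 0:
            sig = sig * math.exp(-config.bleach_rate * t * config.frame_interval)
        if config.poisson_scale > 0:
            sig = rng.poisson(np.clip(sig, 0, None) * config.poisson_scale) / config.poisson_scale
        if config.gaussian_sd > 0:
            sig = sig + rng.normal(0.0, config.gaussian_sd, size=sig.shape)
        data[t] = np.clip(sig, 0.0, None)
    vs = VolumeSeries(data, config.voxel_size, config.frame_interval)
    lv = LabelVolume(labels, config.voxel_size, config.frame_interval,
                     track_ids={i + 1: i + 1 for i in range(truth.n_nuclei)})
    return vs, lv


# ---------------------------------------------------------------------------
# FRAP curve synthesis
# ---------------------------------------------------------------------------

@dataclass
class FrapTruthConfig:
    """Generative twin of the one-phase-association recovery model.

    The post-bleach normalized curve is
    ``N(t) = plateau * (1 - exp(-k t))`` (bleach depth 1 at t=0) scaled so
    prebleach sits at ``prebleach_level``; the immobile fraction is
    ``(prebleach_level - plateau) / prebleach_level``.
    """

    prebleach_level: float = 1.0
    bleach_depth: float = 1.0  # fraction of prebleach removed at t=0
    k: float = math.log(2) / 10.0  # 1/s
    plateau: float = 0.8  # normalized units
    noise_sd: float = 0.0
    n_timepoints: int = 60
    dt: float = 1.0  # s
    n_prebleach: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.plateau <= self.prebleach_level):
            raise ValueError("need 0 <= plateau <= prebleach_level")
        if self.k <= 0 or self.dt <= 0:
            raise ValueError("k and dt must be positive")

    @property
    def t_half(self) -> float:
        return math.log(2) / self.k

    @property
    def immobile_fraction(self) -> float:
        return (self.prebleach_level - self.plateau) / self.prebleach_level


def generate_frap(config: FrapTruthConfig) -> dict:
    """Synthesize a FRAP series with known kinetics.

    Returns a dict with the normalized curve and a raw two-region series
    (``Ip``, ``Ap``, ``Inp``, ``Anp``, ``b``) algebraically consistent with
    the two-region normalization, so normalization can be tested
    round-trip: ``(Ip - b) * Ap / ((Inp - b) * Anp)`` reproduces ``N(t)``.
    """
    rng = np.random.default_rng(config.rng_seed)
    n0 = config.prebleach_level * (1.0 - config.bleach_depth)
    t_post = np.arange(config.n_timepoints) * config.dt
    n_curve = n0 + (config.plateau - n0) * (1.0 - np.exp(-config.k * t_post))
    t_pre = -np.arange(config.n_prebleach, 0, -1) * config.dt
    pre = np.full(config.n_prebleach, config.prebleach_level)
    times = np.concatenate([t_pre, t_post])
    n_all = np.concatenate([pre, n_curve])
    if config.noise_sd > 0:
        n_all = n_all + rng.normal(0.0, config.noise_sd, size=n_all.shape)
    prebleach = np.concatenate(
        [np.ones(config.n_prebleach, bool), np.zeros(config.n_timepoints, bool)]
    )
    b, inp, ap, anp = 50.0, 250.0, 80.0, 80.0
    ip = b + n_all * (inp - b) * (anp / ap)
    return {
        "times": times,
        "normalized": n_all,
        "prebleach": prebleach,
        "Ip": ip,
        "Ap": np.full_like(times, ap),
        "Inp": np.full_like(times, inp),
        "Anp": np.full_like(times, anp),
        "background": np.full_like(times, b),
        "truth": {
            "plateau": config.plateau,
            "k": config.k,
            "t_half": config.t_half,
            "immobile_fraction": config.immobile_fraction,
            "prebleach_level": config.prebleach_level,
        },
    }


# ---------------------------------------------------------------------------
# 2D ROI fixtures
# ---------------------------------------------------------------------------

def generate_roi_fixture(
    shape: tuple[int, int],
    background: float = 0.0,
    disks: list[dict] | None = None,
    rectangles: list[dict] | None = None,
) -> tuple[np.ndarray, dict]:
    """Paint disks/rectangles of known value on a uniform background.

    Geometry follows the pixel-center-inclusion rule shared with the ROI
    measurement operators: a pixel belongs to a disk iff its center (at
    ``index + 0.5``) lies within the radius.  Returns the image and a truth
    dict with each painted region's mean (its value) and pixel count.
    """
    img = np.full(shape, float(background))
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy_pix, cx_pix = yy + 0.5, xx + 0.5
    truth: dict = {"background": background, "regions": []}
    for d in disks or []:
        cy, cx = d["center"]
        r = d["diameter"] / 2.0
        mask = (cy_pix - cy) ** 2 + (cx_pix - cx) ** 2 <= r**2
        img[mask] = d["value"]
        truth["regions"].append({"kind": "disk", "mean": d["value"], "n_pixels": int(mask.sum()), **d})
    for r in rectangles or []:
        y0, x0 = r["corner"]
        h, w = r["extent"]
        mask = (cy_pix >= y0) & (cy_pix < y0 + h) & (cx_pix >= x0) & (cx_pix < x0 + w)
        img[mask] = r["value"]
        truth["regions"].append({"kind": "rectangle", "mean": r["value"], "n_pixels": int(mask.sum()), **r})
    return img, truth
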