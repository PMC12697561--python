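# Methods

`nucdyn` quantifies apical–basal nuclear dispersion in columnar epithelia
(the motivating system is the *Drosophila* germband epithelium during
germband extension, whose cells are ~30–35 µm deep) from 4D fluorescence
time-lapse volumes. This note describes each model and procedure, its
assumptions and tunable parameters, what the synthetic-data generator does
and does not emulate, and the numerical choices made where the design was
genuinely open.

## Conventions

Axis order is `(t, z, y, x)`. Depth `z` is measured in micrometers,
positive basally, with the apical surface at `z = 0`; the physical
position of voxel index `i` along an axis of pitch `d` is `(i + 0.5)·d`
(voxel-center, grid-cell convention). Times are seconds internally; speeds
are reported in µm/min.

## Synthetic scenes (`nucdyn.simulate`)

The generator is first-class, tested code: it defines the conditions under
which every downstream stage is validated.

**Geometry.** Ellipsoidal nuclei (default radii `(rz, ry, rx) =
(2.6, 2.2, 2.2)` µm) are placed on a jittered lateral grid inside a cell
of height 32 µm, starting in a common apical plane
(`initial_apical_depth`, default 5 µm, optionally spread). Placement
refuses configurations in which nuclei would clip or crowd the lateral
boundary at t = 0.

**Motion.** Each nucleus is assigned one of three classes
(`motion_mix`, default 50/25/25):

- *active* — constant-velocity basal runs at `run_speed` (default
  0.5 µm/min, matching the ~0.4–0.5 µm/min scale of actively transported
  nuclei in this tissue) alternating with pauses; dwell times are
  exponential with means `run_duration_s` (120 s) and `pause_duration_s`
  (30 s), for a mean speed of ~0.4 µm/min at the default duty cycle.
  `pause_duration_s = 0` gives uninterrupted ballistic motion. Live-imaging
  studies of this tissue report only the observable speeds, not the dwell
  statistics of nuclear runs, so the dwell defaults are stand-ins, not
  estimates.
- *diffusive* — isotropic Gaussian random walk with per-axis coefficient
  `diffusion_coeff` (0.1 µm²/min), so `MSD(τ) = 2·D·τ` per axis.
- *confined* — discretized mean-reverting (Ornstein–Uhlenbeck) walk with
  relaxation time `confinement_tau_s` (20 s) and stationary SD equal to
  half the hard bound `confinement_radius` (0.5 µm), with excursions
  clipped at the bound.

`z` reflects at 0 and at `cell_height`: nuclei cannot cross the apical
surface, but nothing in the generator keeps them out of the apical 2 µm,
so exclusion-zone invasion is simulable.

**Rendering.** Nuclei are rasterized by voxel-center inclusion, blurred by
a Gaussian PSF (default σ = (0.5, 0.3, 0.3) µm), optionally dimmed by
`exp(−bleach_rate·t)`, optionally Poisson-resampled, and corrupted with
additive Gaussian read noise (clipped at 0). Ground-truth label volumes
are rendered without blur or noise; overlapping nuclei are allowed but
recorded in `truth.overlap_pairs`. The generator makes no claim to optical
realism beyond a Gaussian PSF: no spherical aberration, no depth-dependent
attenuation, no camera gain maps, no membrane channel. Consequences for
interpretation: passing tests demonstrate correct recovery of the stated
generative models, not robustness to aberrated or under-sampled real data.

**FRAP curves.** The generative twin of the recovery model:
`N(t) = N0 + (plateau − N0)(1 − e^(−kt))` post-bleach, a flat prebleach
level before, Gaussian noise on `N`, and a raw two-region series
(`Ip, Ap, Inp, Anp, b`) constructed to be algebraically consistent with
the normalization formula so normalization can be tested round-trip.

## Segmentation and tracking (`nucdyn.segmentation`)

Pipeline: resample → smooth → local-threshold → erode to seeds → gradient
watershed → overlap linking.

- *Isotropic resampling.* Linear interpolation along z with the
  grid-cell convention: `nz` slices at pitch `dz` span `nz·dz` µm and
  become `round(nz·dz/dx)` slices at the lateral pitch.
- *Local threshold.* Foreground iff intensity exceeds the local mean over
  a cubic window (default 7 µm, ~1.5 nuclear diameters) plus
  `local_offset` times the global robust (1st–99th percentile) intensity
  range. An all-equal volume yields an empty mask.
- *Seeds.* Binary erosion by a ball (default 1.2 µm). Components whose
  seed vanishes but hold ≥ `min_seed_voxels` are re-seeded at their
  interior distance-transform maximum. Components with multiple
  well-separated EDT maxima (minimum separation `min_peak_separation`,
  default 2.2 µm ≈ one nuclear radius; relative height ≥ 0.5) are treated
  as fused nuclei and re-seeded with one marker per maximum — an automated
  replacement for interactive seed editing, flagged in the returned
  metadata.
- *Watershed.* Seeded watershed of the Sobel gradient magnitude restricted
  to the rough mask (the background is never flooded), since nuclear edges
  carry the steepest intensity change; labels partition the mask.
- *Linking.* A label at t+1 inherits the track of the t-label with maximal
  voxel overlap provided `overlap/size(t+1) ≥ min_overlap_fraction`
  (default 0.3); candidates are taken greedily by overlap, ties broken by
  centroid distance, so inheritance is injective. Unmatched labels start
  new tracks rather than guessing.

Numerical defaults (`gaussian_sigma = 0.4` µm, `local_offset = 0.25`) were
calibrated on the package's synthetic scenes (40 nuclei, SNR 5, 1-µm z
spacing), where they give detection precision = recall = 1.0 and mean
IoU ≈ 0.86 across seeds. They are starting points for real data, not
measurement-independent constants.

## Midplane positioning (`nucdyn.geometry`)

Columnar-epithelium nuclei are often top-heavy, so the widest z-plane is a
biased positional readout. The *nuclear midplane* is instead the midpoint
between the two half-maximum crossings of the per-plane
cross-sectional-area profile. Implementation choices:

- Half-max crossings are located by linear interpolation between adjacent
  z-samples (sub-slice precision at 1-µm spacing); the flanks used are the
  outermost crossings, and plateau maxima therefore need no special
  peak-location rule.
- A profile that touches either end of the volume at or above half-max has
  an unlocatable flank; the nucleus is marked invalid (NaN) for that frame
  and excluded from population metrics, never silently placed.
- The midplane depends only on profile shape (invariant to uniform area
  scaling) and is exactly equivariant under rigid basal shifts.

Depth categories: exclusion zone (≤ 2 µm), apical10 (≤ 10 µm — the apical
third of a ~30–35-µm cell), basal (> 10 µm). Exclusion-zone membership is
a subset of apical10; fractions divide by the valid population per frame,
so `apical10 + basal = 1` identically. The apical reference is tissue-wide
(top edge of the apical-most foreground slice, or a caller-supplied plane);
a per-cell reference is not implemented because the synthetic scenes have
a single flat apical surface — callers with curved tissue should pass
their own reference per nucleus.

## Motion metrics (`nucdyn.motion`)

Trajectories (midplane depth preferred, centroid z otherwise) are
denoised with a fifth-order sliding median (edges padded by repetition),
then analyzed two ways:

- *Velocities.* Apical–basal displacement over a sliding 1-min window,
  in µm/min; each nucleus contributes its mean and peak speed.
- *Rolling-window MSD.* In every window of `W` consecutive points
  (default `W = 15`, ~3.5 min at 15-s sampling) the time-averaged MSD over
  all overlapping pairs is computed for lags 1..W−1, and the power-law
  exponent γ of `MSD(τ) ∝ τ^γ` is the unweighted OLS slope of log MSD vs
  log τ over integer lags `4..⌊3(W−1)/4⌋` (lags 4..10 at W=15). The lower
  cutoff excludes the first three lags, which are dominated by
  localization-noise artifacts; the estimator is exact on pure power laws
  and scale-invariant by construction. Windows with any non-positive MSD
  in the fitted range get γ = NaN and are excluded from classification.

**Active classification.** A window is active when γ > 1; an *active
interval* is a run of at least `min_run` consecutive active windows, and a
nucleus is active when it has at least one interval. `min_run` defaults to
12 windows (~ one window span, ~3 min): adjacent rolling windows share
W−1 points, so γ estimates are strongly autocorrelated, and median-filtered
stationary (confined) tracks exhibit spurious γ > 1 runs of up to ~11–13
windows; requiring ~W consecutive active windows reduces the confined
false-positive rate to <1% while ballistic tracks remain active in every
window. Per-track outputs also carry a `min_run = 1` variant for
sensitivity analysis. Genuinely Brownian tracks are intrinsically
ambiguous under this criterion (roughly half show a qualifying run); the
classifier separates directed from confined motion, not directed from
diffusive.

`percent_active` divides active nuclei by nuclei with at least one defined
γ; nuclei with no defined γ are excluded from the denominator.

## FRAP analysis (`nucdyn.frap`)

Normalization corrects focal-plane and biological drift with one or two
non-photobleached reference regions:
`N = (Ip − b)·Ap / ((Inp − b)·Anp)`; with two references their
background-subtracted area-weighted intensities are averaged before
division. Time points where the reference falls to the background are
rejected and flagged. `N` is invariant to a common gain on all
intensities.

The post-bleach curve is fitted to a one-phase association
`N(t) = N0 + (plateau − N0)(1 − e^(−kt))` by nonlinear least squares
(`k > 0` bound). The bleach-frame acquisition (t = 0) is excluded.
Initialization is derivative-free and robust: plateau from the
last-quartile mean, `k = ln2 / (time to half-plateau)`, N0 from the first
post-bleach sample. Derived quantities: `t50 = ln2/k` and immobile
fraction `(prebleach − plateau)/prebleach`, which reduces to plain
subtraction when prebleach is normalized to 1 but remains a fraction when
it drifts; overshoot (plateau above prebleach) is reported as a negative
value, not clipped. Both the raw-prebleach and rescaled-to-1 fitting
conventions are supported (`rescale_prebleach`), and the prebleach level
used is always reported. Reaction–diffusion models, double exponentials,
and bleach-spot profile corrections are out of scope.

## ROI quantitation (`nucdyn.quant`)

Pixel membership is by center inclusion (a pixel belongs to an ROI iff its
center at `index + 0.5` satisfies the geometry) with no anti-aliased
partial pixels, so every mean is exactly reproducible by brute-force pixel
enumeration — the property the tests exploit. Operators:

- disk and rectangle means; freehand-style ring means (pixels within half
  the stroke width of a closed polyline, default 3 px);
- t0-baseline normalization `(mean − bg) / (baseline_t0 − baseline_bg)`;
- concentric-disk local background for centrosomal spots (15/25-px
  diameters defined at 0.168 µm/px and rescaled for other calibrations):
  background = (ID_large − ID_small)/(A_large − A_small), subtracted from
  the small-disk mean; exactly invariant to adding a constant to the image;
- exponential bleach correction: frame means fitted to `a·e^(−bt) + c`,
  frames divided by `fit(t)/fit(0)`; a failed fit falls back to ratio
  correction and is flagged;
- 3-px line scans sampled bilinearly at pixel pitch with the stroke mean
  taken across perpendicular offsets;
- ROUT-style outlier removal: robust location (median) and scale (68.27th
  percentile of absolute residuals, corrected by n/(n−1)), two-sided
  t-scores, and a Benjamini–Hochberg step at FDR rate Q (default 1%).
  This is an approximation — the originating software's exact formulation
  is proprietary — but it reproduces the operational behavior on
  univariate samples: clean Gaussian data lose ≤ 2·Q·n points, large
  spikes are always removed, and removals are reported, never silent.
  Samples below n = 10 are left untouched and flagged.

## Problem sizes used in the tests

The validation suite runs on scenes sized for a single CPU: the
segmentation benchmark uses 40 nuclei in a 32×112×168-voxel anisotropic
grid (SNR 5), tracking uses 9 nuclei over 20 frames, motion-class
recovery uses 100 trajectories of 60 frames per class, and FRAP recovery
uses 50 replicate curves of 60 s. These sizes give stable statistics for
the stated tolerances; all are configuration parameters, and larger scenes
only cost time.

## Known limitations

- Segmentation assumes nuclei are the only bright objects; there is no
  membrane channel and no cell segmentation.
- The apical reference is tissue-wide; strongly curved epithelia need a
  caller-supplied per-nucleus reference.
- The active/diffusive boundary of the γ > 1 criterion is soft (see
  above); percent-active comparisons are meaningful between conditions
  analyzed with identical `W`, `min_run`, and sampling interval.
- The bleach-correction model is single-exponential with offset; two-phase
  bleaching is not modeled.
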