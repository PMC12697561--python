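# nucdyn

Quantitative analysis of microtubule-driven **nuclear dispersion** in
columnar epithelia from 4D fluorescence time-lapse volumes — built for the
developmental-biology setting in which nuclei start in a common apical
plane and are actively transported basally (e.g. the *Drosophila* germband
epithelium, ~30–35 µm deep, during germband extension).

The package is a Python library with a built-in synthetic-data generator,
so every stage is testable against known ground truth without any image
download. It provides:

- **Synthetic scenes** (`nucdyn.simulate`) — ellipsoidal nuclei moving by a
  mixture of active (run/pause), diffusive, and confined motion; anisotropic
  voxels, Gaussian PSF, Poisson/Gaussian noise, optional photobleaching;
  FRAP curves and ROI fixtures with exact truth.
- **3D segmentation & tracking** (`nucdyn.segmentation`) — isotropic
  resampling, Gaussian preprocessing, local-threshold rough masks,
  erosion-derived seeds with automated fused-nucleus splitting, seeded
  watershed on the gradient magnitude, and maximal-overlap track linking.
- **Apical–basal positioning** (`nucdyn.geometry`) — the nuclear
  *midplane*, defined as the midpoint between the two half-maximum
  crossings of the per-plane cross-sectional-area profile
  (robust for top-heavy nuclei), and population fractions in the apical
  exclusion zone (≤ 2 µm), the apical 10 µm, and the basal cytoplasm.
- **Motion metrics** (`nucdyn.motion`) — 1-min-window apical–basal
  velocities (mean/peak per nucleus), fifth-order median prefiltering, and
  rolling-window MSD classification: within each window of W points,
  `MSD(τ) ∝ τ^γ` is fitted by an unweighted log–log least-squares slope
  over integer lags `4..⌊3(W−1)/4⌋`, and sustained `γ > 1` marks active
  transport.
- **FRAP kinetics** (`nucdyn.frap`) — two-region drift-corrected
  normalization `N = (Ip−b)·Ap / ((Inp−b)·Anp)`, one-phase-association
  fitting `N(t) = N0 + (plateau−N0)(1−e^{−kt})`, half-time `t50 = ln2/k`,
  and immobile fraction (prebleach − plateau).
- **ROI quantitation** (`nucdyn.quant`) — disk/ring/rectangle/line ROIs
  with exact pixel-center geometry, t0 normalization, concentric-disk
  (15/25 px) local-background correction for centrosomal spots,
  exponential bleach correction, and ROUT-style (FDR) outlier removal.

A thin `nucdyn` CLI exposes the pipeline stages (`simulate`, `segment`,
`metrics`, `msd`, `frap-fit`, `quantify`, `run-all`); the library API and
the `examples/` scripts are the primary interface.

## Worked example

`examples/msd_active_motion.py` simulates 50 depth trajectories per motion
class (60 frames at 15 s, 0.05 µm localization noise), median-filters
them, and runs the rolling-window MSD classification:

```text
    active: mean gamma  1.98, 100.0% of nuclei active, mean 1-min speed 0.50 um/min
 diffusive: mean gamma  0.85,  56.0% of nuclei active, mean 1-min speed 0.29 um/min
  confined: mean gamma  0.05,   0.0% of nuclei active, mean 1-min speed 0.16 um/min
```

Ballistic runs give γ ≈ 2, Brownian motion γ ≈ 1, confined motion γ ≪ 1;
the programmed 0.5 µm/min run speed is recovered exactly by the 1-min
velocity window. `examples/segment_and_track.py` scores the full
segmentation pipeline against ground truth:

```text
segmented 9 tracks over 10 frames
frame 0: precision 1.00, recall 1.00, mean IoU 0.72
tracking: 81/81 links correct (100.0%)
```

and `examples/frap_kinetics.py` fits noisy recovery curves at the two
kinetic regimes typical of centrosomal (fast, small immobile pool) versus
perinuclear (slow, ~40% immobile) microtubule populations:

```text
  centrosome-like: t50   4.8 s (truth   5.1), immobile fraction 0.15 (truth 0.15)
 perinuclear-like: t50  16.3 s (truth  18.2), immobile fraction 0.42 (truth 0.40)
```

The other examples cover scene generation, midplane/category metrics, and
ROI quantitation. `docs/methods.md` documents the models, parameters,
defaults, and limitations.

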