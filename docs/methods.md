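# Methods

This note describes the models and procedures `rtnf` implements, the
defaults it chooses where the underlying experimental description
leaves the design open, and what the synthetic-data generator does and
does not emulate.

## Paradigm schedules

Both built-in schedules are gap-free sequences of half-open condition
blocks totalling 370 s = 185 volumes at TR = 2 s. Volume *i*
represents the acquisition interval [i·TR, (i+1)·TR) and takes the
condition of the block containing its start time; indices are 0-based
and all API times are seconds. The quoted run length of the original
experiment exceeds 185×2 s by a few seconds of pre-scan time; the
schedule models exactly the 185 acquired volumes, since the volume
count is the operative quantity everywhere downstream.

## Hemodynamic model

The canonical double-gamma HRF is the difference of two gamma
densities, response peak at 6 s and undershoot peak at 16 s (both
dispersions 1 s², undershoot ratio 1/6, 32-s support), normalized to
unit peak. The gamma shape is delay/dispersion + 1 so the density
mode falls exactly at the stated delay. Condition regressors are
unit-height boxcars convolved with this kernel; the analysis samples
them at TR resolution, while the simulator convolves on a 0.2-s grid
and normalizes the response to unit peak, so an injected amplitude of
*a* percent produces a peak intensity change of exactly *a* percent of
baseline. The deliberate grid mismatch means the analysis regressors
are not trivially identical to the simulated response — parameter
recovery is tested to 15 %, not machine precision.

## Synthetic data

Per region with baseline intensity *B* (default 1000 a.u.):

    s_t = B·(1 + drift_t + global_t)·(1 + Σ_c a_c/100·resp_c(t)) + e_t

* **Noise** is AR(1) (coefficient 0.3 by default) scaled to a
  stationary SD of `noise_sd` percent of baseline (default 0.5 %).
  AR(1) is the simplest serially correlated model; the original data's
  noise spectrum is not characterized, so these are fixture choices,
  not estimates.
* **Drift** is a 120-s-period cosine plus a linear term, peak
  amplitude `drift_amplitude` percent (default 0.5 %).
* **Global fluctuation** is multiplicative and shared across regions
  and voxels (smoothed white noise, SD `global_sd` percent, default
  0.3 %). Because it is shared and multiplicative, the feedback
  signal's background subtraction cancels it exactly, making the
  cancellation identity testable rather than approximate.
* **Displacement traces** are smoothed noise (≈0.05 mm scale) plus an
  optional task-locked component controlled by `motion_coupling`.

Not emulated: cardiac/respiratory physiology, rigid-body motion
geometry, EPI artifacts, spatial heterogeneity of the HRF. Passing
tests therefore demonstrate correctness of the computation chain under
a plausible signal model, not performance on real scanner data.

### Group generator

TE is linear in the injected think amplitude, so a single calibration
factor (noise-free TE of a 1 % amplitude, computed once per schedule
and cached) maps a desired TE to the amplitude that produces it. The
printed group parameters — parallel 1.27 (0.8), serial 2.3 (1.0) —
are sample statistics of one observed table, so the generator
moment-matches: per-group normal draws of best-run TE are
standardized to the requested sample mean and SD, with the draw
spread deflated by the Monte-Carlo-estimated TE estimation SD at the
configured noise level so the *realized* (estimated) TEs carry the
requested spread. Each subject's remaining 17 run amplitudes sit at
least 1 % (amplitude units) below the best run with a further uniform
spread, which keeps the most-efficient-run selection well posed; the
best run's position is uniform over the 18 runs.

## Online feedback

The feedback signal at a displayed volume is the target-ROI percent
signal change minus the whole-brain-background percent signal change,
each referenced to the mean of a baseline window: the 5 volumes of the
preceding "feedback count" block (serial) or 10 volumes of the
preceding "count" block (parallel). The parallel count block holds 15
volumes; the *last* 10 are used, allowing hemodynamic settling (which
10 the original system used is not recorded). In the first cycle no
control block has completed yet, so the tail of the initial baseline
block is used with the same window length. The thermometer maps
[−fs_max, +fs_max] linearly onto 21 levels with 0 % at level 10 and
clamps beyond; fs_max defaults to 2 % and the exact display scaling of
the original system is not recorded. The parallel paradigm's ~10-s
display lag is a presentation property, exposed as an optional trace
shift rather than baked into the signal computation.

## Training efficiency

The ROI GLM uses condition regressors plus an intercept — no
derivatives or motion terms (those belong to the map-level model).
Contrasts: "think" (parallel; count is the implicit baseline) and
"think > count" (serial). Contrast estimates convert to PSC by
scaling with the peak height of the positively weighted part of the
contrasted regressor and dividing by the run mean intensity; using
the positive part keeps the two paradigms' contrasts on the same
scale, which is what makes TE comparable across groups. TE ties are
broken by the earliest run (deterministic, follows training
chronology).

## Group statistics

Shapiro–Wilk, Welch's t (Welch–Satterthwaite df), and Mann–Whitney U
with midranks, tie-corrected normal approximation and continuity
correction when ties are present (the mETR positions are tied
integers), exact enumeration for small tie-free samples. scipy
provides the distributions; the module owns validation, table
handling and reporting.

## Whole-brain analysis

* Smoothing: separable Gaussian, σ = FWHM/(2√(2 ln 2)) per axis in mm,
  reflecting boundaries.
* High-pass: projection onto the complement of a drift basis holding a
  linear trend plus all DCT components slower than the cutoff
  (default 0.01 Hz). The explicit linear term removes linear scanner
  drift exactly; a truncated cosine set alone leaves a ~2 % residual.
* Motion exclusion: Pearson correlation of each subject's scan-to-scan
  displacement with the think regressor; subjects above Q1 + 1.5·IQR
  of the group's correlations are excluded (as printed; a flag
  switches to the conventional Q3 + 1.5·IQR upper fence). Constant
  traces have undefined correlation and are flagged for review.
* First level: least-squares-all — one regressor per think repetition
  (6 parallel, 8 serial), a combined count regressor, a combined
  feedback regressor (serial), temporal derivatives of all regressors
  of interest (contrast weight 0), and 6 or 24 motion confounds
  (params, squares, one-frame lags, lagged squares). Contrast
  positive weights sum to 1 and count enters at −1; count is modeled
  explicitly so that weight is well defined, and equivalence with the
  implicit-baseline parameterization is asserted on fixtures.
  Voxelwise t converts to z by matched upper-tail quantiles applied
  sign-symmetrically, capped at |z| = 40.
* Group level: voxelwise one-sample OLS t across subject contrast
  maps, Gaussianized to z. Mixed-effects weighting and random-field
  cluster correction are deliberately replaced by this OLS model
  paired with sign-flip permutation FWE — exact at the problem sizes
  this package targets and free of closed-form approximations. Zero-
  variance voxels receive the z cap directly.
* Cluster inference: face (6-neighbor) connectivity; the null is the
  maximum supra-threshold cluster size under per-subject sign flips,
  enumerated exhaustively whenever 2^n does not exceed the requested
  permutation count (then p-values are exact and the identity pattern
  is counted once), otherwise Monte-Carlo with the +1/+1 correction.
  Defaults: cluster-forming Z > 3.1 at α = 0.05; conjunction
  (voxelwise minimum of two group z maps, groups flipped
  independently) at Z > 2.3, α = 0.01; disjunction re-thresholds a
  map after exclusively masking conjunction voxels at Z > 3.1,
  α = 0.05.

A practical note on the permutation null: with n = 8 subjects there
are 256 sign patterns, so the smallest attainable corrected p is
1/256 ≈ 0.004. If between-subject variance is unrealistically small,
single-flip patterns still cross the cluster-forming threshold and no
cluster can reach α = 0.01; test fixtures therefore carry realistic
between-subject noise.

## Labeling

Functional labeling correlates the unthresholded group z map with each
template weight map over the intersection of their masks (Pearson r,
invariant to positive affine transforms of the map); operating on the
unthresholded map uses both extent and level of activation, and a
thresholded-map option is available since the original toolbox
configuration is not recorded. Synthetic template sets are smoothed,
standardized random fields (approximately decorrelated); the
probabilistic atlas is a set of Gaussian bumps normalized to a
sub-partition. Real network atlases are user-supplied at runtime —
the shipped stand-ins are synthetic and the original study's
correlation values are not reproducible from them. Structural
parcellation binarizes each atlas region at P ≥ 0.25 and tallies
supra-threshold voxels and peak statistic per region; the tri-color
overlap map labels conjunction voxels "both" and each disjunction's
voxels as paradigm-specific, partitioning the union of the inputs.

## Problem sizes and determinism

All analyses run on desk-scale grids (6³–10³ voxels for map tests,
185-volume runs, 10+10-subject groups, 200–1,000 replicate
simulations) — sizes chosen so the full chain, including exhaustive
permutation enumeration, is exact and fast. Every stochastic
component takes an explicit seed; identical seeds give bit-identical
outputs, and the study pipeline writes a manifest linking every
artifact to its configuration and seed.
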