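# Methods

## The statistic

Lesion network mapping estimates, from healthy subjects' resting-state
data, the connectivity pattern a lesioned region had before it was
damaged: seed the lesion mask in each matched control's cleaned BOLD run,
Fisher-Z transform the voxel-wise Pearson correlations, and merge the
per-(lesion, control) maps into a group **lesion network (LN) template**.
The merge is a per-voxel ordinary least squares of the Fisher-Z values on
the control's age and maximum head motion (mean-centred), gender, imaging
site, and the lesion identity (both sum-to-zero coded factors); the model
intercept is the covariate-adjusted grand mean and is taken as the LN.

**Lesion network similarity (LNS)** then scores every brain voxel of a
patient visit by how much its own connectivity fingerprint resembles the
LN: the voxel's whole-brain FC profile (Fisher-Z correlation with every
other brain voxel, the seed itself excluded) is correlated with the LN
template over the same seed-excluded support, clipped to |r| ≤ 0.999 and
Fisher-Z transformed.  A voxel with high LNS is behaving, network-wise,
like the lesioned region once did — the operational signature of
functional compensation.  The statistic applies identically to control
runs, giving the healthy reference level.

Per-visit LNS maps are modelled voxel-wise with a linear mixed-effects
model,

    similarity ~ ADL + age + gender + max_head_motion + (1 | subject),

ADL being the activities-of-daily-living score (0–100) at that visit.
Compensation predicts a *negative* ADL effect: as recovery proceeds, the
borrowed network role is relinquished.  Voxel-wise tests are corrected by
cluster extent calibrated with Monte-Carlo simulation of null fields
matching the residuals' spatial autocorrelation.

## Preprocessing and quality control

Frame censoring flags timepoints whose frame-to-frame 6-parameter
displacement exceeds a step limit (default 0.5 mm; both frames straddling
the motion are removed) or whose signal-outlier fraction exceeds a limit
(default 0.10).  Rotations are converted to millimetres as arc length on
a 50 mm sphere before any norm is taken.  Three run-level inclusion
criteria are strict inequalities: more than 4.7 minutes must survive
censoring; maximum pairwise 6-D head motion below 2 mm; censored fraction
below 20%.  The comparisons are made after rounding away sub-nanometre
float fuzz so that a run at exactly a printed boundary is excluded.
Patients need at least two usable visits to stay in the study.

Cleaning is a single least-squares projection on the kept timepoints
whose design spans a constant, a linear trend, the six motion parameters
and their first differences, optional tissue regressors, and sine/cosine
pairs for every DFT frequency outside the 0.009–0.08 Hz passband — the
censoring-compatible equivalent of separate nuisance regression plus
bandpass filtering.  Collinear design columns are dropped with a warning.
Spatial smoothing (default FWHM 5 mm) is a mask-renormalised Gaussian:
values outside the brain mask never bleed in, and a scalar offset
restores each volume's in-mask mean exactly, which keeps global
normalisation stable for the correlation stages.  Because smoothing is
spatial and the projection temporal, the two commute; re-projecting
cleaned data with the same design is a no-op to machine precision.

## Matching

Each patient is matched to k = 3 controls without replacement by a
logistic propensity model of group membership on age, gender, and maximum
head motion (patients contribute the motion averaged over their three
scans).  Matching is greedy nearest-neighbour on |score difference|,
patients in ascending id order, ties broken by ascending control id;
without-replacement is forced by the design arithmetic (17 patients × 3 =
51 distinct controls).  Perfect separation of the logistic fit falls back
to an L2-penalised Newton solve with a warning.  Imaging site is *not* a
matching covariate but is retained for the LN covariate adjustment.

## Mixed-effects engine

All voxels share one fixed-effects design and one grouping structure, so
REML is profiled over the variance ratio λ = τ²/σ²: for fixed λ the GLS
whitening is a per-subject partial demeaning, the two log-determinant
terms are voxel-independent, and only the per-voxel residual sum of
squares varies.  λ is optimised on {0} ∪ 49 log-spaced points in
[10⁻³, 10³] with a parabolic refinement in log λ, then exact per-voxel
GLS estimates are computed at the optimum (voxels grouped by their λ).
This reproduces statsmodels MixedLM to ~10⁻⁶ on the study design while
fitting thousands of voxels per second on one CPU; MixedLM remains the
independent cross-check in the test suite.

Wald t-tests on the ADL coefficient use between-within degrees of
freedom, df = n_obs − n_fixed − n_subjects + 1 — closed-form and accurate
for 17 subjects × 3 visits (type-I error 0.049, CI coverage 0.951 in the
calibration suite).  Voxels whose λ̂ hits the zero boundary revert to
plain OLS with classical standard errors and df = n_obs − n_fixed,
flagged in the results object; classical (not cluster-robust) errors are
used there because the sandwich is anti-conservative at 17 clusters and
the OLS route preserves the exact identity partial η² = t²/(t² + df) =
SS_effect/(SS_effect + SS_residual).  Constant covariate columns (e.g. an
all-male cohort draw) are dropped with a warning; voxels with non-finite
responses return NaN statistics rather than failing the fit.

Effect sizes are partial η² = t²/(t² + df).  Predicted connectivity maps
at ADL levels 47/65/83 are β₀ + β_ADL·L with the other covariates at
their sample means; the model is affine in ADL, so the middle map equals
the voxel-wise mean of the outer two — a property the tests assert
exactly.

## Cluster-extent correction

Residual spatial smoothness is summarised by the mixed autocorrelation
model ACF(r) = a·exp(−r²/2b²) + (1−a)·exp(−r/c), fitted by bounded least
squares to residual correlations at integer-voxel lags along each axis.
The *equivalent FWHM* reported for an ACF is the FWHM of the Gaussian
kernel producing it (√2 × the ACF half-radius) combined in quadrature
with the voxel width, since a voxel is itself a voxel-sized boxcar —
hence unsmoothed white noise on a 3 mm grid reports ≈3 mm rather than
zero, and noise smoothed to a 6 mm total reports ≈6 mm.

Null fields are generated by Fourier colouring: the target spectrum is
the DFT of the periodic ACF kernel (negatives clipped), and fields are
scaled by the theoretical variance so their marginals are exactly
N(0, 1).  Thresholding each of n_iter fields two-sided at the voxel p,
and recording the largest face-adjacent (6-connectivity) cluster inside
the brain mask, yields the smallest extent k with P(max ≥ k) ≤ α.
Cluster tables report unweighted centre-of-mass coordinates in the RAI
sign convention (negative x = subject right), volumes in mm³, and signed
peak statistics.  Face-only connectivity and two-sided thresholding are
the conservative choices; FWER calibration is verified at the analysis'
realistic smoothness (≈8 mm equivalent FWHM) where the integer cluster
threshold is fine-grained enough for the empirical rate to sit near α.

## The synthetic cohort

No patient data are redistributable, so the package ships a generator
whose defaults *are* the emulated study conditions: 17 patients × 3
visits plus a 120-control pool; 130 volumes at TR = 3 s; ADL rising
32.2 ± 6.3 → 75.3 ± 18.2 → 88.4 ± 16.8 across visits (per-patient draws
sorted to keep trajectories monotone, clipped to [0, 100]); ages
63.2 ± 9.1 (patients) and 61.0 ± 14.3 (pool); patient max head motion
0.79 ± 0.64 mm versus 0.59 ± 0.39 mm in the pool, realised by scaling a
6-parameter random walk to the drawn target exactly.

The brain is a 24×28×24 grid of 3 mm voxels with an ellipsoidal mask
carrying a latent network: disjoint spherical nodes mixing a bank of
band-limited (0.01–0.08 Hz) unit-variance Gaussian latent time courses,
plus white noise (signal SD 2.0 vs noise SD 1.0, giving within-network
voxel correlations ≈0.5–0.65, typical of smoothed resting-state data).
Design choices that make the statistic observable at desk scale, fixed
before the acceptance suite was written:

- **The lesion has a network.**  Non-compensation nodes' mixing weights
  overlap the lesion node's with ρ ~ U(0.35, 0.8) — they are the "R"
  regions the lesion is genuinely connected to.  Without this the LN
  template is a bare lesion self-peak and profile similarity carries no
  signal.
- **Focal lesion, broad network.**  The lesion region (radius 4 mm) is
  smaller than the network nodes (radius 6 mm), so the template norm is
  not dominated by the seed's self-correlation peak.
- **Compensation by construction.**  A compensation node's weights are
  s·w_lesion + √(1−s²)·w_own with w_own ⊥ w_lesion, so its noiseless
  signal correlates with the lesion node's at exactly s.  In patients the
  lesion node emits pure noise (it is not functioning); in controls it
  functions normally, which is what lets the LN be estimated from them.
- **s is tied to ADL.**  s = clip(a + b·ADL) with the line anchored at
  s = 0.75 for the visit-1 mean ADL and s = 0.40 for the visit-3 mean —
  the planted decay the corrected analysis must recover.  A constant
  schedule (b = 0) provides the matching null condition.

Every random quantity derives from one master seed; per-run seeds come
from a CRC-32 hash of (subject id, visit), so any single BOLD run
regenerates bit-identically in isolation and full cohorts never need to
be held in memory.

What the generator does **not** emulate: haemodynamic response shapes,
physiological noise and scanner drift, anatomical tissue classes (the
"tissue" nuisance input is synthetic), per-patient lesion anatomy (all
patients share the one planted lesion region), and spatial normalisation
— the upstream registration steps are out of scope and data are born on a
common grid.  Passing tests therefore demonstrate the pipeline's
statistical behaviour (calibration, recovery, invariances), not
robustness to registration or physiological artefacts.

A note on absolute similarity values: voxels *inside* the planted network
legitimately score high LNS (their own-region profile entries align with
the template), so the planted compensation seed is the top voxel outside
the network rather than the global maximum; detection of compensation
rests on the ADL trend, not on absolute ranking.

## Problem sizes used in the shipped studies

The full-scale configuration (24×28×24 grid, 17 patients, 120-control
pool, 1000 Monte-Carlo iterations) is used by the acceptance script's
single end-to-end run.  The replicated planted-recovery study uses a
reduced condition chosen to keep 40 replicates tractable on a laptop —
14×16×14 grid, 12 patients, 38-control pool, 9 nodes of radius 5 mm,
lesion radius 3.5 mm, 300 Monte-Carlo iterations — with 20 replicates per
arm (decaying vs constant planted similarity).  Calibration studies use
200 simulated cohorts (mixed-effects) and 1000 + 500 null fields
(cluster threshold).

## Known limitations

- The LN merge is additive OLS per voxel; no interactions or weights.
- Random intercepts only; three visits cannot support random slopes.
- The ACF is assumed stationary and isotropic over the mask.
- Greedy matching is order-dependent by construction; the documented
  id-ordering makes it deterministic rather than optimal.
- Similarity values are reported on both the Fisher-Z and r scales; the
  field's reporting convention varies, so tables carry both.
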