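# Methods

## Scope and data flow

The package analyses multi-parametric quantitative MRI of retroperitoneal
sarcoma at the whole-tumor level: per-voxel parameter estimation from 4D
magnitude series, first-order histogram summaries over a volume of interest
(VOI) assembled from per-slice ROIs, double-baseline repeatability, cohort
and per-patient response assessment, and rank-correlation of co-located
imaging and histopathology values. Because the clinical images live in a
controlled-access repository, all inputs are produced by the `phantom`
module, which is first-class, tested code: it generates digital tumors and
tables with the statistical structure the analysis assumes.

## Signal models

- Diffusion (ADC series): S(b) = S0·exp(−b·ADC), b in s/mm², ADC in mm²/s.
- Diffusion (IVIM series): S(b) = S0·[(1 − f)·exp(−b·D) + f·exp(−b·D*)],
  the standard two-compartment intra-voxel incoherent motion form in which
  f is the perfusion volume fraction and D* the pseudo-diffusion
  coefficient. The protocol modelled acquires *separate* DWI series for ADC
  and for IVIM, so the phantom synthesises both.
- Relaxometry: S(TE) = S0·exp(−TE·R2*), TE in seconds, R2* in 1/s.
- Dixon: fat = S0·FF, water = S0·(1 − FF); FF = fat/(fat + water).
- Contrast: post = pre·(1 + e) with enhancement fraction e per voxel;
  ε_F = (post − pre)/(post + pre) = e/(2 + e).

## Phantom defaults (the simulated study conditions)

- Grid: ellipsoidal sub-regions in voxel-index space (0-based, axial slices
  along the last axis), piecewise-homogeneous per tissue class
  (cellular, myxoid, fibrous, fat, necrotic). Class parameter values sit
  inside the ranges reported for retroperitoneal sarcoma cohorts: median
  ADC spanning ~0.95–2.77×10⁻³ mm²/s, f of a few percent, D* of tens of
  10⁻³ mm²/s, R2* ~5–58 s⁻¹, and fat fraction up to ~0.85 for
  well-differentiated liposarcoma.
- Encodings: b = {0, 50, 100, 200, 400, 600, 900} s/mm² and
  TE = {5, 10, 15, 20, 25, 30} ms by default, both configurable; the b list
  covers the b = 0 needed by IVIM and the b = 50 floor used for ADC.
- Noise: Rician magnitude noise, sqrt((S + n₁)² + n₂²) with n₁, n₂ ~
  N(0, σ). The default level is set via a target ROI SNR of 386 (the
  estimator 0.66·S_tumor/SD_background applied to the lowest-b image; the
  0.66 factor undoes the Rayleigh reduction of the background magnitude
  SD, so σ ≈ S_tumor/SNR).
- Fat suppression: fat-class voxels are attenuated by a multiplicative
  factor (default 0.05) in the DWI and GRE series only, so that the
  signal-intensity threshold has genuine suppressed-fat voxels to exclude.
- Double-baseline cohort: 27 patients by default; per patient a true
  log-value ~ N(ln 1.70×10⁻³, 0.2), two baseline replicates each adding
  N(0, s_W) on the log scale with s_W = 0.025 (the value implied by a
  2.5% CoV), and an optional post-treatment log-shift.
- Histology tables: a Gaussian copula couples the nuclear-to-stromal-ratio
  latent to the (ADC, D) latents and the histology fat-fraction latent to
  the imaging-FF latent. Spearman targets (defaults −0.42, −0.45, +0.79)
  are converted to latent Pearson correlations via r = 2·sin(π·ρ_s/6); the
  NSR latent is solved as the linear combination of the ADC and D latents
  (themselves correlated at 0.9) that achieves both targets jointly, and
  infeasible target triples raise. Marginals are strictly monotone in the
  latents, so targets are exact population rank correlations.

What the phantom does **not** emulate: partial-volume mixing at region
boundaries, within-class parameter heterogeneity, k-space/coil effects,
motion, distortion, or B0/B1 bias. Passing tests therefore demonstrate the
correctness of the estimators and statistics under the stated models, not
robustness to those real-data effects.

## Voxel-wise fitting

**Thresholding.** Voxels whose lowest-encoding signal falls below k·σ
(default k = 3) are excluded from ADC/IVIM/R2* fitting, removing
suppressed fat.

**Mono-exponential (ADC, R2*).** Per voxel, Levenberg–Marquardt least
squares on (S0, rate), initialised at the closed-form log-linear solution
(OLS of ln S on the encoding over positive samples). The ADC fit uses
b ≥ 50 s/mm² by default (configurable). Voxels with all-zero signal, a
failed optimisation or a strictly negative rate are invalidated rather
than clamped; a zero rate (constant signal) is a legitimate estimate.
Negative rates within 10⁻¹⁰ of zero are treated as an exactly-zero rate
(optimizer round-off).

**IVIM by MCMC.** All masked voxels are sampled simultaneously by a
component-wise adaptive random-walk Metropolis sampler vectorised over
voxels, in the transformed coordinates (ln S0, ln D, logit f, ln D*) with
the Jacobian of the transform applied so that priors are uniform in
natural units: D ∈ [0.1, 4]×10⁻³ mm²/s, f ∈ [0, 0.5],
D* ∈ [3, 300]×10⁻³ mm²/s, S0 positive-flat, with D* > D enforced. The
likelihood is Gaussian; at an SNR of several hundred the Rician/Gaussian
discrepancy is negligible (documented limitation at low SNR). When no
noise level is supplied it is estimated per voxel from the residuals of
the initialisation and floored at 10⁻⁴ of the voxel's peak signal so that
noiseless input yields a sharply peaked but still samplable posterior.

Initialisation is a segmented fit (high-b log-linear for D, intercept gap
for f, log-spaced D* grid with S0 profiled analytically) refined by
bounded least squares. The curvature of the sum of squares at that mode
sets per-voxel, per-coordinate posterior scales used both to disperse the
chains and to seed the proposal widths (2.4× the scale), which are then
adapted toward 44% acceptance during burn-in and frozen afterwards.

Defaults are 3 chains × 4000 steps with 1000 burn-in. Shorter desk-scale
runs (e.g. 2000 steps) produce accurate posterior medians but flag ~20% of
voxels purely through sampling autocorrelation in the convergence
diagnostic; 4000 steps reduces spurious flags to ~2% at a cost of seconds
for the vectorised sampler. Convergence is declared per voxel when the
rank-normalised split R-hat, taken as the worst case over ln D, logit f
and ln D*, is ≤ 1.05; non-convergent voxels are invalidated and counted.
Point estimates are posterior medians pooled over chains. Chains are
bit-reproducible under a fixed seed.

**Derived maps.** FF, EF and ε_F follow the definitions above. EF's 5%
criterion is relative to the pre-contrast signal (voxels with zero
pre-contrast signal cannot enhance by a relative criterion and remain in
the denominator); both EF and ε_F are invariant to a common rescaling of
the pre and post volumes.

## VOI summaries

Per-slice ROIs are unioned and, when grids differ, transferred by
nearest-neighbour lookup of voxel centres (shared field of view assumed).
Statistics are computed over valid fitted voxels only; tumor volume counts
every VOI voxel. Centiles interpolate linearly between order statistics;
skew and kurtosis are moment-based with the Pearson kurtosis convention
(normal → 3) and are reported as NaN for a constant map; the SD uses
ddof = 1. A tumor (or histology ROI) with mean fat fraction strictly above
0.80 is excluded from diffusion and R2* analyses but retained for fat
analysis.

## Repeatability

With d_i = ln x_i2 − ln x_i1 over N patients: s_W = sqrt(Σd_i²/2N),
CoV = 100·sqrt(exp(s_W²) − 1), LoA± = 100·(exp(±1.96·√2·s_W) − 1); the
1.96·√2 factor is kept literal rather than re-derived from a
t-distribution. Statistics that can be negative (skew, kurtosis) use the
untransformed path, LoA = mean(d) ± 1.96·SD(d).

Confidence intervals use the chi-squared pivot for a duplicate design,
N·s_W²/σ_W² ~ χ²(N), propagated through the monotone CoV/LoA transforms
(the interval for the lower LoA reverses, since it decreases in s_W). This
is a standard construction for a within-subject SD from duplicates; it is
a documented, swappable choice rather than a reproduction of any specific
published CI recipe. A simulation test at the 27-patient cohort size
checks that the CI covers the generating CoV at ~95%.

An individual post-treatment percentage change is called a significant
increase/decrease when it falls strictly outside the upper/lower 95% LoA.

## Hypothesis tests

- Signed-rank (paired): zero differences are dropped (flagged when all are
  zero, p = 1 by convention). For up to 25 informative pairs the null is
  exact — the distribution of the positive-rank sum over all 2^N sign
  assignments of the |d| midranks, computed by a shift-polynomial
  convolution (midranks doubled to integers, so ties are handled) — with
  two-sided p = min(1, 2·min(P(W ≤ w), P(W ≥ w))). Beyond 25, a
  tie-corrected normal approximation (no continuity correction).
- Rank-sum (two groups): exact permutation null over all C(n_A+n_B, n_A)
  assignments via subset-count dynamic programming when min(n) ≤ 10 and
  the total ≤ 20; tie-corrected normal approximation otherwise.
- Spearman: average ranks for ties; exact full-permutation p for n ≤ 9,
  t-approximation otherwise; 95% CI by Fisher z with variance
  1.06/(n − 3). The nuclear-to-stromal ratio is ln-transformed before
  correlation (rank correlations are unaffected; fitted lines and plots
  are not). Fibrous-stroma contrasts binarise grades {1, 2} vs {3–5}.
- Significance is two-sided p < 0.05 with no multiplicity correction, as
  is conventional for exploratory imaging-biomarker panels of this size;
  this is documented rather than hidden.

Response reporting includes a volume-change surrogate (median and range of
percentage volume change, count increasing) explicitly labelled non-RECIST:
RECIST 1.1 requires radiologist diameter readings, which are out of scope.

## Problem sizes and determinism

Demo-scale defaults keep every stage desk-sized: phantoms of ~10³ tumor
voxels (32×32×10 grids), repeatability simulations of 10⁴ patients,
error-rate simulations of 2×10³ replicates, and histology tables of
48–500 ROIs. All stochastic stages take a single seed; the pipeline writes
a JSON manifest (package and library versions, seeds, thresholds, artifact
list) that fully determines its outputs, and repeated runs with the same
configuration are byte-identical in their CSV outputs.

## Known limitations

- The Gaussian likelihood in the IVIM sampler biases estimates at low SNR
  where Rician noise is markedly non-Gaussian.
- f and D* are weakly identified at small perfusion fractions; their
  posteriors are broad and their test-retest repeatability is accordingly
  poor. This mirrors clinical experience and is why acceptance tolerances
  for f and D* are looser than for D.
- The nearest-neighbour VOI transfer assumes a shared field of view and
  does not perform registration.
- The histology coupling model is a copula on ranks; it reproduces rank
  correlations, not the joint physical distribution of tissue properties.
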