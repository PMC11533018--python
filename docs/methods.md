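# Methods

This note documents the models implemented in `ironmap`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical corner cases. Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Units and constants

Susceptibility is carried in ppb everywhere; conversion to frequency uses
γ̄ = 42.576 MHz/T, so at B₀ = 7 T one ppb corresponds to
γ̄·B₀·10⁻⁹ ≈ 0.298 Hz. Echo times enter all fits in seconds, so R2\* is in
s⁻¹. The default echo train is 10 echoes at TE = 1.68 + k·3.05 ms
(k = 0..9, last echo 29.13 ms), 0.8 mm isotropic voxels, B₀ along the
third axis.

## Digital phantom

A brain-shaped ellipsoid (semi-axes 33 × 36 × 33 mm on a 96³ grid — a
desk-scale stand-in that preserves the acquisition's voxel size while
keeping FFTs fast) contains seven bilateral ellipsoidal DGM structures
placed mirror-symmetrically about the mid-sagittal plane. Default
susceptibilities are the female linear age models evaluated at age 65
(putamen 31.6, caudate 36.0, globus pallidus 89.3, accumbens −3.3,
amygdala −15.3, hippocampus −15.0, thalamus −16.5 ppb relative to
background tissue at 0 ppb). R2\* is tied to χ by the affine map
R2\* = max(5, 30 + 0.5·χ_ppb) s⁻¹ — both proxies track tissue iron, and
this keeps all decays resolvable within the 29.13 ms echo train. M0 is
100 inside the brain with a 3% smooth seeded texture. Structure placement
keeps every DGM ellipsoid at least ~5 mm from the brain boundary so that
spherical-mean-value kernels of useful radius fit around it; placement
is otherwise schematic, not anatomical.

Construction is strict: overlapping structures or structures poking out of
the brain raise errors naming the offender, and the left/right masks are
exactly mirror images (voxel centers are symmetric about the mid-sagittal
plane for even grids).

## Forward simulation

The field is computed by FFT convolution with the dipole kernel
D(k) = 1/3 − (k·b̂)²/|k|², D(0) = 0, after zero-padding the grid by a
factor 2 to suppress circular wrap-around. The noiseless signal per voxel
and echo is M₀·exp(−R2\*·TE)·exp(i·2π·Δf·TE); complex Gaussian noise of
equal variance per channel is added, with SNR defined as the mean
first-echo brain magnitude over the per-channel noise SD. The forward
field was validated against the closed-form external field of a uniformly
magnetized sphere (within 0.5% at two radii from the center; the test
allows 5%).

## QSM reconstruction

1. **Unwrapping.** The true-phase Laplacian is obtained from the wrapped
   phase ψ as cos ψ·∇²(sin ψ) − sin ψ·∇²(cos ψ) with a DCT spectral
   Laplacian (Neumann boundaries) and inverted by a Poisson solve. The
   estimate is refined three times by re-unwrapping the wrapped residual,
   its global offset is aligned to the circular mean of ψ − estimate (the
   raw Poisson solution is zero-mean, which can park the offset exactly
   between two 2π congruence classes), and the result is snapped to the
   value congruent with ψ. Wherever the refined estimate is within π of
   the truth this is exact; a 6π linear ramp and smooth multi-wrap fields
   unwrap to machine precision, verified against scikit-image's
   path-following unwrapper as an independent oracle.
2. **Field fit.** Per-voxel weighted linear least squares of unwrapped
   phase vs TE with weights = magnitude²; slope/2π is the frequency, the
   intercept (receiver phase) is discarded, and the weighted RMS residual
   (rad) is kept. Voxels with residual > 0.3 rad are excluded by the
   reliability mask and never interpolated.
3. **Background removal.** V-SHARP: for each radius r from 12 mm down to
   2 mm, the field is high-pass filtered by (δ − S_r) on the mask eroded
   by r and deconvolved by (1 − S̃_r) with truncated inversion
   (components with |1 − S̃_r| < 0.01 are zeroed); each voxel takes the
   result from the largest radius whose sphere fits inside the mask. Two
   details matter: the deconvolution is per-radius (a single
   largest-radius deconvolution under-restores boundary-adjacent
   structures by a further 20–25%), and the smallest radius is 2 mm — a
   1 mm sphere at 0.8 mm voxels contains too few voxels to act as a
   spherical mean and leaves the background field in place near the
   boundary. The output lives on the mask eroded by 2 mm. On the default
   phantom, fields from purely external sources are suppressed to < 2%
   RMS, and an interior source's field is preserved at a projection
   coefficient of 0.92 within its ROI.
4. **Dipole inversion.** Plain TKD: χ(k) = F(k)/D(k) where |D| ≥ δ, else
   F(k)/(δ·sign D), sign(0) = +1. The default is δ = 0.05 with the
   V-SHARP truncation at 0.01. Uncorrected TKD attenuates ROI means by
   roughly the central PSF response (≈ 0.82 at δ = 0.2, ≈ 0.96 at
   δ = 0.05); since this package reports absolute ROI values against a
   known truth and applies no post-hoc PSF rescaling, the small δ is the
   configuration under which the chain meets its ≤ 15% ROI-recovery
   contract (measured: 5.9–12.8% over the seven structures, noiseless,
   rank order preserved). δ remains configurable for users who prefer the
   conventional 0.1–0.2 range and can tolerate the attenuation.
5. **Referencing.** Optional subtraction of the brain-mean (idempotent).
   It is the default for cohort work, where only contrasts matter and
   negative ROI medians imply some reference; recovery tests against the
   phantom use `reference="none"` because the truth's scale is absolute
   (background ≡ 0 ppb) and a mean shift is ill-conditioned for the
   near-zero accumbens (±0.5 ppb moves it by 15%).

## R2\* mapping

Magnitude-squared-weighted log-linear least squares initializes a
vectorized damped Gauss–Newton refinement of S(TE) = M₀·exp(−R2\*·TE)
(30 iterations, steps clipped to ±50 s⁻¹ and ±2 in log M₀). Noiseless
data is recovered exactly (the log model is then exactly linear and the
refinement has zero gradient). Negative rates are clamped to 0 with M₀
refit in closed form, and flagged; all-zero voxels are dropped from the
mask. No Rician noise-floor term: at SNR 50 and a 29 ms echo train the
high-SNR assumption holds (median DGM error 2.5% in the seeded tests),
and a floor model would trade transparency for little accuracy here.

## ROI statistics

`trim_and_mean` computes μ and the population (1/n) σ once, keeps values
in the closed interval [μ−2σ, μ+2σ], and averages — a single pass, no
re-iteration; σ = 0 keeps everything, fewer than 2 values is an error.
On Gaussian data this removes ≈ 4.6% of voxels. Hemispheres are compared
with a two-sided Wilcoxon signed-rank per ROI and metric (all-zero
differences give p = 1 by convention; fewer than 5 pairs is flagged) and
merged as the unweighted mean of the two trimmed means, propagating a
lone hemisphere with a flag. Volume–metric association reports both
Pearson and Spearman coefficients, for raw volume and volume/TIV.

## Cohort simulator

Seventy-seven subjects by default: 40 women, 37 men; ages uniform within
tertiles [54, 62), [62, 69), [69, 78] allocated 24/26/27 by largest
remainder (applied per sex, which reproduces the overall counts). Per
subject, ROI and metric the bilateral value is
intercept + slope·age + N(0, sd) from the sex-specific linear model, with
sd = slope_SE·√Σ(ageᵢ − mean age)² — the OLS identity inverted, so refits
reproduce the published slope SE in expectation (verified to within 20%
across 200 seeds). Left/right values are v ± a with
a ~ N(0, sd/4): a symmetric split whose merge returns exactly v, and no
systematic lateralization. Risk flags are drawn so CRS scores 0/1/2 occur
in proportion 40/20/17, with BMI consistent with the obesity flag;
16 of 77 subjects carry ApoE ϵ4 (one homozygote); ROI volumes and TIV are
drawn independently of the metric values (a built-in null for the
volume-correlation check). Group effects are multiplicative on the
affected subjects' values, so a factor 1.217 shifts the group median by
+21.7%.

Deliberate simplifications: ROI noise is independent across ROIs and
metrics (no within-subject covariance), residuals are Gaussian, ages are
uniform within tertiles, and no covariate couples to the iron values
except through the injected effects. Passing tests therefore show that
the statistical machinery recovers what the models encode — not that real
brains satisfy these models.

`null_models()` zeroes every slope and gives both sexes a common
intercept per ROI/metric, keeping the calibrated noise: the configuration
under which every one of the 112×2 tests is truly null, used to measure
the family-wise error of the corrected pipeline (≤ 0.05 plus binomial
tolerance over 200 seeds).

## Statistical layer

Age tertiles use half-open bins (boundary ages go to the older-starting
group, the last bin closed); overweight is BMI strictly > 25; ApoE
carriage is ≥ 1 ϵ4 allele; CRS is the count of five risk flags. The
comparison plan enumerates 3 age pairs, 1 sex pair, 6 age-within-sex
pairs, 1 ApoE pair, 3 CRS pairs (scores 0/1/2 pairwise) and 2
overweight-within-sex pairs — 16 pairs, ×7 ROIs = 112 tests per metric.
Mann–Whitney U uses the exact null distribution when n_a·n_b ≤ 400 and
the pooled sample is tie-free, otherwise the normal approximation with
tie and continuity corrections (verified against brute-force enumeration
for all group sizes up to 7). Bonferroni correction is min(1, 112·p);
raw and corrected values are both reported. Percent differences are
100·(median_b − median_a)/|median_a| — the absolute-value denominator
keeps the sign of the difference when a median is negative. OLS
regressions (scipy's linregress) are verified against the closed-form
normal equations to 1e-10.

One estimator property worth knowing: the percent difference of sample
medians at group sizes 57 vs 17 has a small positive bias (≈ +0.8
percentage points at the default generator, measured over 2000 seeds)
and a per-cohort SD of ≈ 24 points, because a 17-subject median is noisy
and the denominator is itself random. Averages over seeds converge to
the estimator's expectation, not exactly to the injected shift.

## Problem sizes and determinism

Defaults keep everything single-CPU friendly: the phantom pipeline runs
a 96³ grid (≈ 12 s for the full QSM chain), slope-recovery suites use
200 simulated cohorts, and the family-wise-error suite 200 seeds; these
sizes give Monte-Carlo SEs comfortably inside the tolerances they are
tested at. Every stochastic stage takes an explicit integer seed
(numpy `default_rng`); identical configurations produce byte-identical
CSV outputs, and each pipeline run writes a manifest with SHA-256 hashes
of its artifacts.

## Known limitations

- No k-space sampling, coil combination, GRAPPA or motion: the simulator
  produces ideal voxel signals, so reconstruction errors here are a lower
  bound on real-data errors.
- TKD without PSF rescaling under-recovers by design at larger δ; the
  chain is deterministic and oracle-checkable, but an iterative
  regularized inversion would behave differently near the magic-angle
  cone.
- Cortical/boundary accuracy is out of scope: the eroded output mask
  drops a 2 mm rim, and boundary-adjacent values are filtered with small
  SMV radii.
- Segmentation is assumed given (the phantom's labels are exact); no
  registration step exists.
- The cohort simulator models marginal ROI distributions only; any
  analysis exploiting cross-ROI covariance would need a richer generator.
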