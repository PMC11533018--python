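# ironmap

Brain-iron quantification in deep gray matter (DGM) with 7 T MRI, end to
end: a digital phantom with known susceptibility and relaxation rates, a
quantitative susceptibility mapping (QSM) and R2\* reconstruction pipeline,
outlier-trimmed ROI statistics, and the cohort-level analysis of healthy
aging (sex-specific age regressions and nonparametric group comparisons
with a ×112 Bonferroni correction).

## Who this is for

Iron accumulates in DGM structures (putamen, caudate, globus pallidus, ...)
throughout life and is implicated in neurodegeneration. Two MRI proxies
track it: bulk magnetic susceptibility χ (QSM, in ppb) estimated from the
phase of a multi-echo gradient-echo (MGRE) acquisition, and the apparent
transverse relaxation rate R2\* = 1/T2\* (s⁻¹) estimated from its magnitude
decay. `ironmap` is for researchers who want a reproducible, fully
synthetic test bed for this kind of analysis: every stage can be run
against a ground-truth phantom or a calibrated cohort simulator, so the
whole statistical chain is checkable without any patient data.

## The models at the core

**Forward model.** A susceptibility distribution χ(r) shifts the Larmor
frequency by a convolution with the unit dipole response; in k-space

    Δf(k) = γ̄ B₀ · D(k) · χ(k),   D(k) = 1/3 − (k·b̂)²/|k|²

with γ̄ = 42.576 MHz/T, so 1 ppb ↦ ≈ 0.298 Hz at 7 T. The complex MGRE
signal per voxel and echo time TE is `M₀ · exp(−R2*·TE) · exp(i·2π·Δf·TE)`
(ten echoes, TE₁ = 1.68 ms, ΔTE = 3.05 ms, 0.8 mm isotropic).

**Reconstruction.** Laplacian phase unwrapping → magnitude²-weighted linear
fit of phase vs TE (field map, with a residual-based reliability mask) →
variable-radius spherical-mean-value background removal (V-SHARP) →
thresholded k-space division (TKD) dipole inversion → optional referencing
to the brain mean. R2\* comes from a weighted log-linear fit refined by
Gauss–Newton on the mono-exponential model.

**ROI statistic.** Each ROI is summarized by the mean of voxel values
inside [μ−2σ, μ+2σ] of its distribution (single pass, population σ); left
and right hemispheres are checked with a Wilcoxon signed-rank test and then
averaged.

**Cohort statistics.** Per ROI, sex and metric, ordinary least-squares of
value on age; group differences via two-sided Mann–Whitney U (exact when
n_a·n_b ≤ 400 and tie-free) over 16 group pairs × 7 ROIs = 112 tests per
metric, reported raw and Bonferroni-corrected (×112). The cohort simulator
draws 77 subjects (40 F / 37 M, ages 54–78 in tertiles 24/26/27) from
published sex-specific linear age models with residual noise calibrated so
a refit reproduces the published slope standard errors.

## Worked example

```bash
python analysis/03_simulate_cohort.py --seed 0
python analysis/04_age_regressions.py
```

prints, among the 28 regressions (slopes in ppb/year for QSM, s⁻¹/year for
R2\*):

```
roi_name sex metric    slope  slope_se  p_value  n  reference_slope  slope_dev_se
 putamen   F    qsm    1.723     0.369    0.000 40            1.250         1.284
 caudate   F    qsm    0.856     0.233    0.001 40            0.630         0.969
 caudate   F r2star    0.336     0.130    0.014 40            0.360        -0.181

27/28 fitted slopes within 2 SE of the generating value (single simulated cohort)
```

Each row is one ROI/sex/metric fit on this particular simulated cohort;
`slope_dev_se` is the distance from the generating slope in fitted-SE
units, i.e. single-cohort sampling noise, not bias. Continuing with

```bash
python analysis/05_group_comparisons.py
```

runs the 224 Mann–Whitney tests; on the default seed, 6 survive the ×112
correction — the putamen age contrasts (e.g. +174.7% QSM median between the
youngest and oldest tertile, corrected p = 0.0001) and the amygdala sex
contrast, which is exactly the structure the generating models encode.

The imaging half has the same shape:

```bash
python analysis/01_simulate_phantom.py   # phantom + MGRE acquisition
python analysis/02_reconstruct_maps.py   # QSM + R2* recovery scores
```

On the default phantom the worst-case ROI error of the reconstructed
susceptibility is 12.8% (noiseless) with the ROI rank order preserved, and
R2\* is recovered to 0.2% at SNR 50.

A `ironmap` console script exposes the stages individually
(`simulate-phantom`, `recon-qsm`, `fit-r2star`, `extract-roi`,
`simulate-cohort`, `analyze-cohort`, `run-all`) on NIfTI/CSV files.

## Layout

```
src/ironmap/     geometry, phantom, forward, qsm, relaxometry, roi,
                 cohort, stats, pipeline, io, cli
analysis/        numbered drivers writing tables under results/
tests/           pytest suite (unit, property and acceptance tests)
docs/methods.md  models, parameter choices, numerical details, limitations
```
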