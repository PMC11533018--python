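"""Cohort-level synthetic data: linear age models and subject-table simulation.

The simulator emulates a healthy-aging 7 T cohort of 77 adults aged 54-78
(40 women, 37 men; age tertiles 24/26/27).  Per subject and deep-gray-matter
ROI, QSM (ppb) and R2* (s^-1) values are drawn from published sex-specific
linear age models with Gaussian residuals whose spread is calibrated so an
OLS refit reproduces the published slope standard error in expectation:
for ages a_i, residual_sd = slope_se * sqrt(sum_i (a_i - mean(a))^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

DGM_ROIS = (
    "accumbens",
    "amygdala",
    "caudate",
    "globus_pallidus",
    "hippocampus",
    "putamen",
    "thalamus",
)

AGE_RANGE = (54.0, 78.0)
TERTILE_EDGES = (54.0, 62.0, 69.0, 78.0)
TERTILE_COUNTS = (24, 26, 27)          # of 77
DEFAULT_N_FEMALE = 40
DEFAULT_N_MALE = 37
APOE_CARRIERS = 16                     # of 77, one homozygote
CRS_COUNTS = (40, 20, 17)              # scores 0 / 1 / 2, of 77

RISK_FLAGS = ("hypertension", "diabetes", "dyslipidemia", "smoking", "obesity")

# reference slope/intercept (+- SE) of metric value vs age, per ROI and sex:
# (roi, sex, metric): (slope, slope_se, intercept, intercept_se)
# QSM in ppb and ppb/year, R2* in s^-1 and s^-1/year.
_AGE_MODELS = {
    ("caudate", "F", "qsm"): (0.63, 0.26, -4.97, 17.66),
    ("caudate", "M", "qsm"): (1.09, 0.47, -31.56, 30.48),
    ("putamen", "F", "qsm"): (1.25, 0.33, -49.68, 22.49),
    ("putamen", "M", "qsm"): (1.5, 0.54, -63.11, 34.85),
    ("thalamus", "F", "qsm"): (-0.09, 0.19, -10.64, 12.58),
    ("thalamus", "M", "qsm"): (-0.02, 0.24, -8.23, 15.21),
    ("globus_pallidus", "F", "qsm"): (0.06, 0.56, 85.42, 37.95),
    ("globus_pallidus", "M", "qsm"): (0.54, 0.59, 50.69, 38.37),
    ("hippocampus", "F", "qsm"): (-0.31, 0.18, 5.2, 12.41),
    ("hippocampus", "M", "qsm"): (-0.14, 0.2, -5.02, 12.68),
    ("amygdala", "F", "qsm"): (-0.51, 0.34, 17.88, 23.09),
    ("amygdala", "M", "qsm"): (-0.18, 0.29, -12.78, 18.51),
    ("accumbens", "F", "qsm"): (-1.4, 0.57, 87.74, 38.87),
    ("accumbens", "M", "qsm"): (-0.14, 0.54, -3.17, 35.02),
    ("caudate", "F", "r2star"): (0.36, 0.13, 21.4, 8.89),
    ("caudate", "M", "r2star"): (0.43, 0.19, 20.33, 12.26),
    ("putamen", "F", "r2star"): (0.69, 0.21, 11.67, 14.49),
    ("putamen", "M", "r2star"): (0.72, 0.29, 13.42, 18.79),
    ("thalamus", "F", "r2star"): (-0.07, 0.07, 42.67, 4.67),
    ("thalamus", "M", "r2star"): (-0.02, 0.07, 39.83, 4.3),
    ("globus_pallidus", "F", "r2star"): (0.86, 0.4, 36.23, 27.06),
    ("globus_pallidus", "M", "r2star"): (0.0, 0.45, 88.5, 29.12),
    ("hippocampus", "F", "r2star"): (-0.08, 0.04, 36.17, 2.51),
    ("hippocampus", "M", "r2star"): (0.03, 0.06, 29.4, 3.6),
    ("amygdala", "F", "r2star"): (-0.09, 0.04, 32.56, 2.94),
    ("amygdala", "M", "r2star"): (0.12, 0.05, 19.23, 3.39),
    ("accumbens", "F", "r2star"): (0.12, 0.08, 24.46, 5.23),
    ("accumbens", "M", "r2star"): (0.26, 0.1, 17.15, 6.69),
}

# typical bilateral DGM volumes (mm^3), used for the volume-vs-metric null
_ROI_VOLUMES_MM3 = {
    "accumbens": 1000.0,
    "amygdala": 3200.0,
    "caudate": 7100.0,
    "globus_pallidus": 3100.0,
    "hippocampus": 7400.0,
    "putamen": 9500.0,
    "thalamus": 14500.0,
}


@dataclass(frozen=True)
class LinearAgeModel:
    """Sex-specific linear model of an iron proxy versus age for one ROI."""

    roi_name: str
    sex: str                 # 'F' or 'M'
    metric: str              # 'qsm' (ppb) or 'r2star' (s^-1)
    slope: float             # per year
    intercept: float
    slope_se: float
    intercept_se: float


def load_table1_models() -> list[LinearAgeModel]:
    """The 28 reference linear age models (7 ROIs x 2 sexes x 2 metrics)."""
    return [
        LinearAgeModel(roi_name=roi, sex=sex, metric=metric, slope=s,
                       intercept=b, slope_se=s_se, intercept_se=b_se)
        for (roi, sex, metric), (s, s_se, b, b_se) in _AGE_MODELS.items()
    ]


def null_models() -> list[LinearAgeModel]:
    """Group-effect-free models: zero age slope, sex-shared intercepts.

    Keeps each ROI/metric's printed slope SE (so residual noise is calibrated
    the same way) but removes every systematic difference between groups;
    used to check false-positive control of the comparison machinery.
    """
    out = []
    for m in load_table1_models():
        ref = _AGE_MODELS[(m.roi_name, "F", m.metric)]
        out.append(
            LinearAgeModel(
                roi_name=m.roi_name, sex=m.sex, metric=m.metric, slope=0.0,
                intercept=ref[2] + ref[0] * 65.0,  # common value for both sexes
                slope_se=m.slope_se, intercept_se=m.intercept_se,
            )
        )
    return out


def get_model(roi_name: str, sex: str, metric: str) -> LinearAgeModel:
    s, s_se, b, b_se = _AGE_MODELS[(roi_name, sex, metric)]
    return LinearAgeModel(roi_name=roi_name, sex=sex, metric=metric, slope=s,
                          intercept=b, slope_se=s_se, intercept_se=b_se)


def calibrate_noise(model: LinearAgeModel, ages: Sequence[float]) -> float:
    """Residual SD that makes an OLS refit reproduce the model's slope SE.

    Inverts the OLS identity SE(slope) = sd / sqrt(Sxx) with
    Sxx = sum (age_i - mean(age))^2, so simulated cohorts with these ages
    yield the reference slope SE in expectation.
    """
    ages = np.asarray(ages, dtype=float)
    if np.unique(ages).size < 3:
        raise ValueError("need at least 3 distinct ages")
    sxx = float(np.sum((ages - ages.mean()) ** 2))
    if sxx == 0:
        raise ValueError("ages have zero variance")
    return model.slope_se * np.sqrt(sxx)


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative shift of ROI values for one subject subgroup.

    ``parameter`` is a cohort column ('crs', 'sex', 'apoe_e4_carrier',
    'overweight', ...), ``group`` the value selecting the subgroup.  ``roi``
    and ``metric`` restrict the effect (None = all).  ``factor`` multiplies
    the affected values, so medians shift by (factor-1)*100 percent.
    """

    parameter: str
    group: object
    factor: float
    roi: str | None = None
    metric: str | None = None


class CohortData(NamedTuple):
    cohort: pd.DataFrame      # one row per subject
    roi: pd.DataFrame         # ROITable: L/R trimmed values per subject/ROI/metric
    volumes: pd.DataFrame     # subject_id, roi_name, volume_mm3, tiv_mm3


def _largest_remainder(total: int, weights: Sequence[float]) -> list[int]:
    weights = np.asarray(weights, dtype=float)
    quota = total * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for i in np.argsort(-remainder)[: total - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def _sample_ages(n: int, rng: np.random.Generator) -> np.ndarray:
    """Ages uniform within each tertile, tertile counts proportional to 24/26/27."""
    counts = _largest_remainder(n, TERTILE_COUNTS)
    ages = []
    for (lo, hi), c in zip(zip(TERTILE_EDGES[:-1], TERTILE_EDGES[1:]), counts):
        ages.append(rng.uniform(lo, hi, size=c))
    ages = np.concatenate(ages)
    rng.shuffle(ages)
    return ages


def _assign_risk_profile(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Cardiovascular risk flags with score counts proportional to 40/20/17."""
    score_counts = _largest_remainder(n, CRS_COUNTS)
    scores = np.repeat(np.arange(len(score_counts)), score_counts)
    rng.shuffle(scores)
    flags = np.zeros((n, len(RISK_FLAGS)), dtype=bool)
    for i, s in enumerate(scores):
        if s > 0:
            flags[i, rng.choice(len(RISK_FLAGS), size=s, replace=False)] = True
    out = pd.DataFrame(flags, columns=RISK_FLAGS)
    out["crs"] = flags.sum(axis=1)
    # BMI consistent with the obesity flag (obese -> BMI > 30)
    bmi = np.clip(rng.normal(24.0, 3.0, size=n), 17.0, 29.9)
    bmi[out["obesity"].to_numpy()] = rng.uniform(
        30.5, 36.0, size=int(out["obesity"].sum())
    )
    out["bmi"] = np.round(bmi, 1)
    return out


def _assign_apoe(n: int, rng: np.random.Generator) -> pd.Series:
    n_carriers = int(round(n * APOE_CARRIERS / 77.0))
    genotypes = np.array(["e3/e3"] * n, dtype=object)
    carriers = rng.choice(n, size=n_carriers, replace=False)
    genotypes[carriers] = "e3/e4"
    if n_carriers >= 1:
        genotypes[carriers[0]] = "e4/e4"   # one homozygote in the full cohort
    return pd.Series(genotypes, name="apoe")


def simulate_cohort(
    models: Sequence[LinearAgeModel] | None = None,
    n_female: int = DEFAULT_N_FEMALE,
    n_male: int = DEFAULT_N_MALE,
    group_effects: Sequence[GroupEffect] | None = None,
    seed: int = 0,
    hemisphere_sd_fraction: float = 0.25,
) -> CohortData:
    """Simulate a cohort table plus per-subject, per-ROI iron-proxy values.

    Per subject and model, the bilateral ROI value is
    ``intercept + slope*age + Normal(0, residual_sd)`` with ``residual_sd``
    from :func:`calibrate_noise` on that sex's ages.  Left/right hemisphere
    values are a symmetric split ``v +- a`` with ``a ~ Normal(0,
    hemisphere_sd_fraction * residual_sd)``, so the bilateral mean is exactly
    the generated value.  Group effects multiply matching subjects' values.
    Deterministic per seed.
    """
    if n_female + n_male <= 0:
        raise ValueError("cohort must contain at least one subject")
    if models is None:
        models = load_table1_models()
    rng = np.random.default_rng(seed)

    sexes = np.array(["F"] * n_female + ["M"] * n_male)
    ages = np.empty(len(sexes))
    ages[: n_female] = _sample_ages(n_female, rng) if n_female else []
    ages[n_female:] = _sample_ages(n_male, rng) if n_male else []
    n = len(sexes)
    cohort = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "age": np.round(ages, 2),
            "sex": sexes,
        }
    )
    cohort = pd.concat([cohort, _assign_risk_profile(n, rng)], axis=1)
    cohort["apoe"] = _assign_apoe(n, rng)
    cohort["apoe_e4_carrier"] = cohort["apoe"].str.contains("e4")

    effects = list(group_effects or [])
    for eff in effects:
        if eff.parameter not in cohort.columns and eff.parameter != "overweight":
            raise ValueError(f"unknown grouping parameter: {eff.parameter}")
    overweight = cohort["bmi"] > 25.0

    rows = []
    for model in models:
        in_sex = cohort["sex"].to_numpy() == model.sex
        if not in_sex.any():
            continue
        sub_ages = cohort.loc[in_sex, "age"].to_numpy()
        sd = calibrate_noise(model, sub_ages)
        values = (
            model.intercept
            + model.slope * sub_ages
            + rng.normal(0.0, sd, size=in_sex.sum())
        )
        for eff in effects:
            if eff.roi is not None and eff.roi != model.roi_name:
                continue
            if eff.metric is not None and eff.metric != model.metric:
                continue
            col = overweight if eff.parameter == "overweight" else cohort[eff.parameter]
            selected = (col.to_numpy() == eff.group)[in_sex]
            values[selected] *= eff.factor
        asym = rng.normal(0.0, hemisphere_sd_fraction * sd, size=in_sex.sum())
        n_vox = max(int(_ROI_VOLUMES_MM3[model.roi_name] / 2 / 0.512), 2)
        for sid, v, a in zip(cohort.loc[in_sex, "subject_id"], values, asym):
            for hemi, val in (("L", v + a), ("R", v - a)):
                rows.append(
                    {
                        "subject_id": sid,
                        "roi_name": model.roi_name,
                        "hemisphere": hemi,
                        "metric": model.metric,
                        "trimmed_mean": val,
                        "n_voxels_used": n_vox,
                        "n_voxels_total": n_vox,
                        "flagged": False,
                    }
                )
    roi = pd.DataFrame(rows)

    vol_rows = []
    tiv = rng.normal(1.45e6, 1.2e5, size=n)
    for roi_name, mean_vol in _ROI_VOLUMES_MM3.items():
        vols = rng.normal(mean_vol, 0.10 * mean_vol, size=n)
        for sid, v, t in zip(cohort["subject_id"], vols, tiv):
            vol_rows.append(
                {
                    "subject_id": sid,
                    "roi_name": roi_name,
                    "volume_mm3": max(v, 1.0),
                    "tiv_mm3": t,
                }
            )
    volumes = pd.DataFrame(vol_rows)
    return CohortData(cohort=cohort, roi=roi, volumes=volumes)
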