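"""Cohort statistics: grouping, age regressions, Mann-Whitney comparisons
with a x112 Bonferroni correction, percent differences of group medians.

The testing plan crosses 7 deep-gray-matter ROIs with 16 pairwise group
comparisons drawn from six grouping parameters (age tertiles, sex, age
within sex, ApoE e4 carriage, cardiovascular risk score, overweight within
sex), giving 112 tests per metric; raw and Bonferroni-corrected p-values are
both reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import DGM_ROIS, RISK_FLAGS

BONFERRONI_FACTOR = 112
AGE_GROUP_LABELS = ("54-62", "62-69", "69-78")
PARAMETERS = ("age", "sex", "age_sex", "apoe", "crs", "bmi")
EXACT_MW_MAX_PRODUCT = 400


def compute_crs(flags: Mapping[str, bool]) -> int:
    """Cardiovascular risk score 0-5: count of present risk factors."""
    missing = [f for f in RISK_FLAGS if f not in flags]
    if missing:
        raise ValueError(f"missing risk flags: {missing}")
    return int(sum(bool(flags[f]) for f in RISK_FLAGS))


def assign_age_group(age: float) -> str | None:
    """Tertile label with half-open bins [54,62), [62,69), [69,78]."""
    if 54 <= age < 62:
        return AGE_GROUP_LABELS[0]
    if 62 <= age < 69:
        return AGE_GROUP_LABELS[1]
    if 69 <= age <= 78:
        return AGE_GROUP_LABELS[2]
    return None


def assign_groups(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach the six grouping columns; ages outside [54, 78] are flagged.

    Adds age_group, age_sex_group, apoe_group ('carrier' for >= 1 e4 allele),
    overweight (BMI strictly above 25) and an ``excluded`` flag.  The crs
    column is recomputed from the risk flags when they are present.
    """
    out = cohort.copy()
    out["age_group"] = out["age"].map(assign_age_group)
    out["excluded"] = out["age_group"].isna()
    out["age_sex_group"] = out["sex"] + ":" + out["age_group"].fillna("NA")
    if "apoe_e4_carrier" in out.columns:
        carrier = out["apoe_e4_carrier"].astype(bool)
    else:
        carrier = out["apoe"].str.contains("e4")
        out["apoe_e4_carrier"] = carrier
    out["apoe_group"] = np.where(carrier, "carrier", "non-carrier")
    if all(f in out.columns for f in RISK_FLAGS):
        out["crs"] = out[list(RISK_FLAGS)].astype(bool).sum(axis=1)
    out["overweight"] = out["bmi"] > 25.0
    return out


def fit_age_regression(ages: Sequence[float], values: Sequence[float]):
    """Ordinary least-squares of value on age with slope t-test.

    Returns a dict with slope, intercept, their standard errors, the
    two-sided p-value for slope != 0, and n.
    """
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    if ages.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(ages) == 0:
        raise ValueError("ages have zero variance")
    res = sps.linregress(ages, values)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "slope_se": float(res.stderr),
        "intercept_se": float(res.intercept_stderr),
        "p_value": float(res.pvalue),
        "n": int(ages.size),
    }


def age_regression_table(
    roi_table: pd.DataFrame, cohort: pd.DataFrame,
    metrics: Sequence[str] = ("qsm", "r2star"),
) -> pd.DataFrame:
    """Per-ROI, per-sex OLS of bilateral metric values on age (28 rows)."""
    bilateral = roi_table[roi_table["hemisphere"] == "bilateral"]
    merged = bilateral.merge(cohort[["subject_id", "age", "sex"]], on="subject_id")
    rows = []
    for (roi_name, sex, metric), grp in merged.groupby(
        ["roi_name", "sex", "metric"], sort=True
    ):
        if metric not in metrics:
            continue
        grp = grp.dropna(subset=["trimmed_mean"])
        fit = fit_age_regression(grp["age"], grp["trimmed_mean"])
        rows.append({"roi_name": roi_name, "sex": sex, "metric": metric, **fit})
    return pd.DataFrame(rows)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of group a vs b; returns (U_a, p).

    Exact null distribution when n_a*n_b <= 400 and the pooled sample is
    tie-free, otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size * b.size <= EXACT_MW_MAX_PRODUCT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_raw: float, factor: int = BONFERRONI_FACTOR) -> float:
    """min(1, factor * p)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if not 0 <= p_raw <= 1:
        raise ValueError("p_raw must be in [0, 1]")
    return min(1.0, factor * p_raw)


@dataclass(frozen=True)
class GroupPair:
    """One pairwise comparison: two subgroups defined by column filters."""

    parameter: str
    label_a: str
    label_b: str
    filters_a: tuple[tuple[str, object], ...]
    filters_b: tuple[tuple[str, object], ...]

    def select(self, cohort: pd.DataFrame, which: str) -> pd.Series:
        filters = self.filters_a if which == "a" else self.filters_b
        keep = ~cohort["excluded"] if "excluded" in cohort.columns else pd.Series(
            True, index=cohort.index
        )
        for col, val in filters:
            keep &= cohort[col] == val
        return cohort.loc[keep, "subject_id"]


@dataclass(frozen=True)
class ComparisonPlan:
    rois: tuple[str, ...]
    pairs: tuple[GroupPair, ...]
    pairs_per_parameter: Mapping[str, int] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_tests(self) -> int:
        return len(self.pairs) * len(self.rois)


def comparison_plan(
    rois: Iterable[str] = DGM_ROIS,
    parameters: Iterable[str] = PARAMETERS,
    crs_scores: Sequence[int] = (0, 1, 2),
) -> ComparisonPlan:
    """Enumerate the pairwise group comparisons of the six parameters.

    Age-tertile pairs (3), sex (1), age tertiles within each sex (6),
    ApoE carrier vs non-carrier (1), pairwise CRS scores (3), overweight
    within each sex (2): 16 pairs, 112 tests over 7 ROIs.
    """
    pairs: list[GroupPair] = []
    per_param: dict[str, int] = {}
    for param in parameters:
        start = len(pairs)
        if param == "age":
            for i in range(len(AGE_GROUP_LABELS)):
                for j in range(i + 1, len(AGE_GROUP_LABELS)):
                    a, b = AGE_GROUP_LABELS[i], AGE_GROUP_LABELS[j]
                    pairs.append(GroupPair("age", a, b,
                                           (("age_group", a),),
                                           (("age_group", b),)))
        elif param == "sex":
            pairs.append(GroupPair("sex", "F", "M",
                                   (("sex", "F"),), (("sex", "M"),)))
        elif param == "age_sex":
            for sex in ("F", "M"):
                for i in range(len(AGE_GROUP_LABELS)):
                    for j in range(i + 1, len(AGE_GROUP_LABELS)):
                        a, b = AGE_GROUP_LABELS[i], AGE_GROUP_LABELS[j]
                        pairs.append(GroupPair(
                            "age_sex", f"{sex}:{a}", f"{sex}:{b}",
                            (("sex", sex), ("age_group", a)),
                            (("sex", sex), ("age_group", b)),
                        ))
        elif param == "apoe":
            pairs.append(GroupPair("apoe", "non-carrier", "carrier",
                                   (("apoe_group", "non-carrier"),),
                                   (("apoe_group", "carrier"),)))
        elif param == "crs":
            for i in range(len(crs_scores)):
                for j in range(i + 1, len(crs_scores)):
                    a, b = crs_scores[i], crs_scores[j]
                    pairs.append(GroupPair("crs", f"crs={a}", f"crs={b}",
                                           (("crs", a),), (("crs", b),)))
        elif param == "bmi":
            for sex in ("F", "M"):
                pairs.append(GroupPair(
                    "bmi", f"{sex}:lean", f"{sex}:overweight",
                    (("sex", sex), ("overweight", False)),
                    (("sex", sex), ("overweight", True)),
                ))
        else:
            raise ValueError(f"unknown grouping parameter: {param}")
        per_param[param] = len(pairs) - start
    return ComparisonPlan(rois=tuple(rois), pairs=tuple(pairs),
                          pairs_per_parameter=per_param)


def percent_difference(median_a: float, median_b: float) -> float:
    """100 * (median_b - median_a) / |median_a|; sign follows the difference."""
    return 100.0 * (median_b - median_a) / abs(median_a)


def compare_two_groups(
    values_a: Sequence[float], values_b: Sequence[float],
    factor: int = BONFERRONI_FACTOR,
) -> dict:
    """Medians, percent difference, U statistic, raw and corrected p."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    u, p = mann_whitney(a, b)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    return {
        "median_a": med_a,
        "median_b": med_b,
        "percent_difference": percent_difference(med_a, med_b),
        "u_statistic": u,
        "p_raw": p,
        "p_bonferroni": bonferroni(p, factor),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


def compare_groups(
    roi_table: pd.DataFrame,
    cohort: pd.DataFrame,
    plan: ComparisonPlan | None = None,
    metrics: Sequence[str] = ("qsm", "r2star"),
    factor: int = BONFERRONI_FACTOR,
) -> pd.DataFrame:
    """Run every planned comparison for every ROI and metric.

    Groups with fewer than 3 subjects are flagged but still reported.
    Returns 112 rows per metric under the default plan.
    """
    plan = plan or comparison_plan()
    if "age_group" not in cohort.columns:
        cohort = assign_groups(cohort)
    bilateral = roi_table[roi_table["hemisphere"] == "bilateral"]
    values = bilateral.pivot_table(
        index="subject_id", columns=["roi_name", "metric"],
        values="trimmed_mean",
    )
    rows = []
    for pair in plan.pairs:
        ids_a = pair.select(cohort, "a")
        ids_b = pair.select(cohort, "b")
        for roi_name in plan.rois:
            for metric in metrics:
                col = (roi_name, metric)
                va = values.loc[values.index.intersection(ids_a), col].dropna()
                vb = values.loc[values.index.intersection(ids_b), col].dropna()
                row = {
                    "roi_name": roi_name, "metric": metric,
                    "parameter": pair.parameter,
                    "group_a": pair.label_a, "group_b": pair.label_b,
                }
                if len(va) == 0 or len(vb) == 0:
                    row.update(median_a=np.nan, median_b=np.nan,
                               percent_difference=np.nan, u_statistic=np.nan,
                               p_raw=np.nan, p_bonferroni=np.nan,
                               n_a=len(va), n_b=len(vb), flagged=True)
                else:
                    row.update(compare_two_groups(va, vb, factor))
                    row["flagged"] = min(len(va), len(vb)) < 3
                rows.append(row)
    return pd.DataFrame(rows)
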