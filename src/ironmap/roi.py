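"""Per-subject ROI statistics: outlier-trimmed means, hemisphere handling,
volume correlations.

Each ROI is summarized by the mean of the voxel values retained within
[mu - 2*sigma, mu + 2*sigma] of the ROI distribution (single pass, population
sigma) — discarding partial-volume and vessel voxels while keeping the
high-iron core.  Left/right values are compared with a Wilcoxon signed-rank
test and, absent asymmetry, merged into bilateral means.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phantom import DGM_STRUCTURES, LABEL_CODES

ROI_COLUMNS = [
    "subject_id", "roi_name", "hemisphere", "metric",
    "trimmed_mean", "n_voxels_used", "n_voxels_total", "flagged",
]


def trim_and_mean(values: Iterable[float]) -> tuple[float, int]:
    """Mean of the values inside [mu-2*sigma, mu+2*sigma]; returns (mean, n).

    mu and sigma (population, 1/n) are computed once over the full input; the
    closed interval is applied in a single pass.  sigma = 0 keeps everything.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to trim")
    mu = v.mean()
    sigma = v.std()
    if sigma == 0:
        return float(mu), int(v.size)
    keep = (v >= mu - 2 * sigma) & (v <= mu + 2 * sigma)
    return float(v[keep].mean()), int(keep.sum())


def roi_table(
    map_values: np.ndarray,
    map_mask: np.ndarray,
    labels: np.ndarray,
    reliability: np.ndarray | None,
    metric: str,
    subject_id: str = "sub-000",
    roi_names: Iterable[str] = DGM_STRUCTURES,
    label_codes: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Trimmed mean per ROI and hemisphere from a map plus label volume.

    Voxels outside ``map_mask`` or the reliability mask are excluded before
    trimming.  ROIs with fewer than 2 usable voxels are reported as flagged
    rows with a missing value.  ``label_codes`` maps roi_name -> (left,
    right) integer codes (defaults to the phantom's convention).
    """
    if labels.shape != map_values.shape:
        raise ValueError("labels are not aligned with the map grid")
    codes = LABEL_CODES if label_codes is None else label_codes
    usable = np.asarray(map_mask, bool)
    if reliability is not None:
        usable = usable & np.asarray(reliability, bool)
    rows = []
    for roi_name in roi_names:
        left, right = codes[roi_name]
        for hemi, code in (("L", left), ("R", right)):
            in_roi = labels == code
            vals = map_values[in_roi & usable]
            row = {
                "subject_id": subject_id,
                "roi_name": roi_name,
                "hemisphere": hemi,
                "metric": metric,
                "n_voxels_total": int(in_roi.sum()),
            }
            if vals.size < 2:
                row.update(trimmed_mean=np.nan, n_voxels_used=int(vals.size),
                           flagged=True)
            else:
                mean, n_used = trim_and_mean(vals)
                row.update(trimmed_mean=mean, n_voxels_used=n_used, flagged=False)
            rows.append(row)
    return pd.DataFrame(rows, columns=ROI_COLUMNS)


def hemisphere_test(table: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon signed-rank of left-minus-right per ROI and metric.

    Identical hemispheres give statistic 0 with p = 1 by convention; fewer
    than 5 pairs still runs the exact test but flags the row.
    """
    wide = table[table["hemisphere"].isin(["L", "R"])].pivot_table(
        index=["roi_name", "metric", "subject_id"],
        columns="hemisphere", values="trimmed_mean",
    ).dropna()
    rows = []
    for (roi_name, metric), grp in wide.groupby(level=["roi_name", "metric"]):
        d = (grp["L"] - grp["R"]).to_numpy()
        if np.allclose(d, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.wilcoxon(d, alternative="two-sided")
        rows.append(
            {
                "roi_name": roi_name, "metric": metric, "n_pairs": d.size,
                "statistic": float(stat), "p_value": float(p),
                "flagged": d.size < 5,
            }
        )
    return pd.DataFrame(rows)


def merge_hemispheres(table: pd.DataFrame) -> pd.DataFrame:
    """Bilateral rows: unweighted mean of the left and right trimmed means.

    A missing or flagged hemisphere propagates the present one, flagged.
    """
    rows = []
    grouped = table[table["hemisphere"].isin(["L", "R"])].groupby(
        ["subject_id", "roi_name", "metric"], sort=False
    )
    for (sid, roi_name, metric), grp in grouped:
        vals = grp.loc[~grp["flagged"].astype(bool), "trimmed_mean"].dropna()
        flagged = len(vals) < 2
        rows.append(
            {
                "subject_id": sid, "roi_name": roi_name, "hemisphere": "bilateral",
                "metric": metric,
                "trimmed_mean": float(vals.mean()) if len(vals) else np.nan,
                "n_voxels_used": int(grp["n_voxels_used"].sum()),
                "n_voxels_total": int(grp["n_voxels_total"].sum()),
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows, columns=ROI_COLUMNS)


def volume_metric_correlation(
    volumes: pd.DataFrame, table: pd.DataFrame
) -> pd.DataFrame:
    """Pearson and Spearman correlation of ROI volume (raw and /TIV) vs metric.

    Expects bilateral rows in ``table`` and per-subject ``volumes`` with
    columns subject_id, roi_name, volume_mm3, tiv_mm3.  Zero-variance inputs
    are reported as flagged rows with undefined coefficients.
    """
    bilateral = table[table["hemisphere"] == "bilateral"]
    merged = bilateral.merge(volumes, on=["subject_id", "roi_name"])
    merged = merged.dropna(subset=["trimmed_mean"])
    rows = []
    for (roi_name, metric), grp in merged.groupby(["roi_name", "metric"]):
        y = grp["trimmed_mean"].to_numpy()
        for norm, x in (
            ("volume", grp["volume_mm3"].to_numpy()),
            ("volume_over_tiv", (grp["volume_mm3"] / grp["tiv_mm3"]).to_numpy()),
        ):
            row = {"roi_name": roi_name, "metric": metric, "predictor": norm,
                   "n": len(grp)}
            if np.std(x) == 0 or np.std(y) == 0 or len(grp) < 3:
                row.update(pearson_r=np.nan, pearson_p=np.nan,
                           spearman_r=np.nan, spearman_p=np.nan, flagged=True)
            else:
                pr, pp = sps.pearsonr(x, y)
                sr, sp_ = sps.spearmanr(x, y)
                row.update(pearson_r=float(pr), pearson_p=float(pp),
                           spearman_r=float(sr), spearman_p=float(sp_),
                           flagged=False)
            rows.append(row)
    return pd.DataFrame(rows)
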