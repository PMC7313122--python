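"""Control-vs-diabetic comparison of regional modes.

Each atlas region is tested with a two-sided Wilcoxon rank-sum
(Mann-Whitney U) test on the per-subject regional modes. With 7-vs-8
subjects the exact null distribution is enumerable, so exact p-values are
used whenever the data are tie-free and the combined sample is small;
otherwise midranks with the tie-corrected, continuity-corrected normal
approximation. Raw p drives the significance call at alpha (the study
design's decision rule); Benjamini-Hochberg q-values are reported alongside
so the false-discovery burden of the many-region comparison is visible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Combined-sample-size limit below which the exact null is enumerated.
EXACT_LIMIT = 20


def wilcoxon_rank_sum(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "auto",
) -> tuple[float, float]:
    """Two-sided rank-sum test; returns (U statistic of x, p-value).

    ``method``: "exact" (complete enumeration of rank assignments, requires
    tie-free data), "normal-approx" (midranks, tie correction, continuity
    correction), or "auto" (exact when the combined sample has no ties and
    at most 20 observations, normal approximation otherwise).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if method == "auto":
        method = "exact" if (not has_ties and combined.size <= EXACT_LIMIT) else "normal-approx"
    if method == "exact" and has_ties:
        raise ValueError("exact method requires tie-free data; use normal-approx or auto")
    scipy_method = {"exact": "exact", "normal-approx": "asymptotic"}[method]
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=scipy_method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_regions(mode_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-region group comparison of regional modes.

    Input is the long-format mode table (subject_id, group, region_id,
    region_name, mode_value). Output has one row per region with group
    means/SDs (SD with n-1 denominator), the rank-sum U statistic of the
    control sample, two-sided p, BH q, the significance flag at ``alpha``
    and the direction of the group difference; rows are ranked by ascending
    p-value (ties by region_id) as in the study's result tables.
    """
    rows = []
    for rid, sub in mode_table.groupby("region_id", sort=True):
        ctrl = sub.loc[sub["group"] == "control", "mode_value"].to_numpy()
        diab = sub.loc[sub["group"] == "diabetic", "mode_value"].to_numpy()
        if ctrl.size == 0 or diab.size == 0:
            raise ValueError(f"region {rid}: missing one of the groups")
        u, p = wilcoxon_rank_sum(ctrl, diab)
        cm, dm = ctrl.mean(), diab.mean()
        if cm < dm:
            direction = "control<diabetic"
        elif cm > dm:
            direction = "control>diabetic"
        else:
            direction = "equal"
        rows.append(
            dict(
                region_id=int(rid),
                region_name=sub["region_name"].iloc[0],
                control_mean=cm,
                control_sd=ctrl.std(ddof=1) if ctrl.size > 1 else 0.0,
                diabetic_mean=dm,
                diabetic_sd=diab.std(ddof=1) if diab.size > 1 else 0.0,
                rank_sum_statistic=u,
                p_value=p,
                direction=direction,
            )
        )
    out = pd.DataFrame(rows)
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    out["significant"] = out["p_value"] < alpha
    out = out.sort_values(["p_value", "region_id"], kind="stable").reset_index(drop=True)
    cols = [
        "region_id", "region_name", "control_mean", "control_sd",
        "diabetic_mean", "diabetic_sd", "rank_sum_statistic",
        "p_value", "q_value", "significant", "direction",
    ]
    return out[cols]


def split_tables(comparisons: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into (significant, non-significant) tables; counts sum to all."""
    sig = comparisons[comparisons["significant"]].reset_index(drop=True)
    nonsig = comparisons[~comparisons["significant"]].reset_index(drop=True)
    return sig, nonsig
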