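"""RT-qPCR relative expression (2^-ddCt) and two-group comparison.

Delta-Ct pairs each target measurement with the same sample's reference
assay (technical replicates averaged first); delta-delta-Ct subtracts the
calibrator group's mean delta-Ct.  Group comparison screens each group with
Shapiro-Wilk and uses a Welch t-test when both groups look normal
(P > 0.05), otherwise a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DDCT_COLUMNS = ["sample_id", "group", "assay_id", "dct", "ddct", "rel_expr"]


def ddct(
    table: pd.DataFrame,
    reference_assay: str = "U6",
    calibrator_group: str = "B",
) -> pd.DataFrame:
    """Per-sample relative expression by the 2^-ddCt method.

    ``table`` needs columns sample_id, group, assay_id, ct (an optional
    replicate column marks technical replicates, which are averaged).
    Raises if any sample lacks a reference-assay measurement or the
    calibrator group is absent.
    """
    required = {"sample_id", "group", "assay_id", "ct"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise KeyError(f"qPCR table missing columns {sorted(missing_cols)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    mean_ct = (
        table.groupby(["sample_id", "group", "assay_id"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    ref = mean_ct[mean_ct["assay_id"] == reference_assay].set_index("sample_id")["ct"]
    targets = mean_ct[mean_ct["assay_id"] != reference_assay].copy()
    no_ref = sorted(set(targets["sample_id"]) - set(ref.index))
    if no_ref:
        raise ValueError(f"samples without reference assay {reference_assay!r}: {no_ref}")
    targets["dct"] = targets["ct"].values - ref.loc[targets["sample_id"]].values
    if calibrator_group not in set(targets["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} absent from table")
    calib_mean = (
        targets[targets["group"] == calibrator_group].groupby("assay_id")["dct"].mean()
    )
    targets["ddct"] = targets["dct"].values - calib_mean.loc[targets["assay_id"]].values
    targets["rel_expr"] = 2.0 ** (-targets["ddct"])
    return targets[DDCT_COLUMNS].reset_index(drop=True)


def group_compare(
    rel_expr: pd.DataFrame,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group comparison of relative expression, per assay.

    Shapiro-Wilk screens each group (needs n >= 3); if both pass at
    P > ``normality_alpha`` a Welch t-test is used, otherwise the Wilcoxon
    rank-sum fallback.  Constant groups skip the normality screen and fall
    back to the rank test.  Returns one row per assay with the normality
    p-values, the test used, its p-value and a significance flag.
    """
    rows = []
    for assay, chunk in rel_expr.groupby("assay_id", sort=True):
        groups = sorted(chunk["group"].unique())
        if len(groups) != 2:
            raise ValueError(f"assay {assay}: need exactly two groups, got {groups}")
        x = chunk.loc[chunk["group"] == groups[0], "rel_expr"].to_numpy()
        y = chunk.loc[chunk["group"] == groups[1], "rel_expr"].to_numpy()
        if len(x) < 3 or len(y) < 3:
            raise ValueError(
                f"assay {assay}: Shapiro-Wilk needs >=3 values per group "
                f"(got {len(x)} and {len(y)})"
            )
        degenerate = np.ptp(x) == 0 or np.ptp(y) == 0
        if degenerate:
            sw_x = sw_y = np.nan
            normal = False
        else:
            sw_x = float(stats.shapiro(x).pvalue)
            sw_y = float(stats.shapiro(y).pvalue)
            normal = sw_x > normality_alpha and sw_y > normality_alpha
        if normal:
            test, p = "welch-t", float(stats.ttest_ind(x, y, equal_var=False).pvalue)
        else:
            test, p = "wilcoxon-rank-sum", float(
                stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
            )
        rows.append(
            {
                "assay_id": assay,
                "group_a": groups[0],
                "group_b": groups[1],
                "mean_a": float(x.mean()),
                "mean_b": float(y.mean()),
                "shapiro_p_a": sw_x,
                "shapiro_p_b": sw_y,
                "test": test,
                "pvalue": p,
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)
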