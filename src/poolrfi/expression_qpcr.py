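"""Relative expression by the 2^-ddCt method with a two-group t-test.

Per sample, dCt = Ct(target) - Ct(reference gene); ddCt is the deviation
from the mean dCt of the reference (control) group and relative expression
is 2^-ddCt. The group comparison is Student's equal-variance t-test on dCt
(the log2 scale, where normality is the better assumption); significance
stars follow the 0.05/0.01 convention.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["ddct", "group_ttest", "qpcr_report"]

REQUIRED_COLUMNS = ["sample_id", "group", "gene", "ct_target", "ct_reference"]


def ddct(records: pd.DataFrame, reference_group: str) -> pd.DataFrame:
    """Per-sample relative expression against the reference group's mean dCt.

    ``records`` needs columns sample_id, group, gene, ct_target,
    ct_reference. Samples missing the reference-gene Ct are dropped and
    logged. Returns the input with delta_ct, ddct and rel_expr columns.
    """
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"missing Ct columns: {sorted(missing)}")
    df = records.copy()
    n_bad = int(df["ct_reference"].isna().sum() + df["ct_target"].isna().sum())
    if n_bad:
        logger.warning("dropping %d sample row(s) with missing Ct values", n_bad)
        df = df.dropna(subset=["ct_target", "ct_reference"])
    if reference_group not in set(df["group"]):
        raise ValueError(f"reference group {reference_group!r} absent from data")
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    out = []
    for gene, sub in df.groupby("gene", sort=False):
        for grp, grp_sub in sub.groupby("group"):
            if len(grp_sub) < 2:
                raise ValueError(f"gene {gene!r}: group {grp!r} has < 2 samples")
        ref_mean = sub.loc[sub["group"] == reference_group, "delta_ct"].mean()
        sub = sub.copy()
        sub["ddct"] = sub["delta_ct"] - ref_mean
        sub["rel_expr"] = np.exp2(-sub["ddct"])
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def group_ttest(expressed: pd.DataFrame, reference_group: str) -> pd.DataFrame:
    """Per-gene group comparison on the dCt scale.

    Output: one row per gene per group with mean +/- SD of rel_expr and
    delta_ct, plus the gene-level Student's t p-value and significance stars
    ('*' p<0.05, '**' p<0.01).
    """
    rows = []
    for gene, sub in expressed.groupby("gene", sort=False):
        groups = sorted(set(sub["group"]))
        if len(groups) != 2:
            raise ValueError(f"gene {gene!r}: expected 2 groups, got {groups}")
        other = [g for g in groups if g != reference_group][0]
        a = sub.loc[sub["group"] == reference_group, "delta_ct"]
        b = sub.loc[sub["group"] == other, "delta_ct"]
        t_stat, p = stats.ttest_ind(a, b, equal_var=True)
        if np.isnan(p):
            t_stat, p = 0.0, 1.0
        stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        for grp in (reference_group, other):
            g = sub[sub["group"] == grp]
            rows.append(
                {
                    "gene": gene,
                    "group": grp,
                    "n": len(g),
                    "rel_expr_mean": g["rel_expr"].mean(),
                    "rel_expr_sd": g["rel_expr"].std(ddof=1),
                    "delta_ct_mean": g["delta_ct"].mean(),
                    "delta_ct_sd": g["delta_ct"].std(ddof=1),
                    "t": float(t_stat),
                    "p_value": float(p),
                    "significance": stars,
                }
            )
    return pd.DataFrame(rows)


def qpcr_report(records: pd.DataFrame, reference_group: str) -> pd.DataFrame:
    """Convenience wrapper: ddct then group_ttest."""
    return group_ttest(ddct(records, reference_group), reference_group)
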