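"""Residual feed intake phenotype: regression fit, extremes, pools, summaries.

Residual feed intake (RFI) is the residual of an ordinary least squares fit
of total feed intake on metabolic body weight (initial BW^0.75) and weight
gain. The conventions here: feed conversion ratio (FCR) is computed per bird
as daily feed intake / average daily gain, a single regression is fit over
both sexes, and all ties are broken by ascending bird id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RfiFit",
    "add_derived_traits",
    "fit_rfi",
    "select_extremes",
    "build_pools",
    "group_summary",
]

#: Traits summarized by :func:`group_summary`.
SUMMARY_TRAITS = ["rfi", "dfi", "initial_bw", "final_bw", "adg", "fcr"]


@dataclass(frozen=True)
class RfiFit:
    """OLS fit of total feed intake on (1, BW^0.75, weight gain)."""

    b0: float
    b1: float
    b2: float
    residual_sd: float
    r_squared: float
    n: int

    def predict(self, mbw: np.ndarray, wg: np.ndarray) -> np.ndarray:
        return self.b0 + self.b1 * np.asarray(mbw) + self.b2 * np.asarray(wg)


def add_derived_traits(records: pd.DataFrame) -> pd.DataFrame:
    """Attach wg, adg, dfi, mbw and fcr columns derived from the raw traits."""
    df = records.copy()
    if (df["initial_bw"] <= 0).any() or (df["final_bw"] <= 0).any():
        raise ValueError("body weights must be positive")
    if (df["test_days"] <= 0).any():
        raise ValueError("test_days must be positive")
    df["wg"] = df["final_bw"] - df["initial_bw"]
    df["adg"] = df["wg"] / df["test_days"]
    df["dfi"] = df["total_fi"] / df["test_days"]
    df["mbw"] = df["initial_bw"] ** 0.75
    df["fcr"] = np.where(df["adg"] > 0, df["dfi"] / df["adg"], np.nan)
    return df


def fit_rfi(records: pd.DataFrame) -> tuple[RfiFit, pd.DataFrame]:
    """Fit FI = b0 + b1*BW^0.75 + b2*WG by OLS and fill per-bird RFI.

    Returns the fit and a copy of ``records`` with derived-trait columns and
    an ``rfi`` column (observed minus fitted total feed intake, in grams).
    Raises ``ValueError`` naming the collinear column on a rank-deficient
    design.
    """
    df = add_derived_traits(records)
    n = len(df)
    if n < 3:
        raise ValueError(f"need >= 3 records to fit RFI regression, got {n}")
    X = np.column_stack([np.ones(n), df["mbw"].to_numpy(), df["wg"].to_numpy()])
    rank = np.linalg.matrix_rank(X)
    if rank < 3:
        # identify the offending column by checking rank without each
        names = ["intercept", "mbw", "wg"]
        for j in (1, 2):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"design matrix is rank-deficient: column {names[j]!r}")
        raise ValueError("design matrix is rank-deficient")
    y = df["total_fi"].to_numpy(dtype=float)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    dof = max(n - 3, 1)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    fit = RfiFit(
        b0=float(beta[0]),
        b1=float(beta[1]),
        b2=float(beta[2]),
        residual_sd=float(np.sqrt(ss_res / dof)),
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        n=n,
    )
    df["rfi"] = resid
    return fit, df


def select_extremes(
    records: pd.DataFrame, n_per_tail: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split off the ``n_per_tail`` lowest- and highest-RFI birds.

    Ties crossing the cut are resolved deterministically by ascending bird id
    and logged.
    """
    if "rfi" not in records.columns:
        raise ValueError("records need an 'rfi' column; run fit_rfi first")
    n = len(records)
    if n_per_tail > n // 2:
        raise ValueError(f"n_per_tail={n_per_tail} exceeds half of {n} records")
    asc = records.sort_values(["rfi", "bird_id"], kind="mergesort")
    low = asc.head(n_per_tail)
    high = asc.tail(n_per_tail).sort_values(
        ["rfi", "bird_id"], ascending=[False, True], kind="mergesort"
    )
    for group, name in ((low, "low"), (high, "high")):
        boundary = group["rfi"].iloc[-1] if name == "low" else group["rfi"].iloc[-1]
        n_tied = int((records["rfi"] == boundary).sum())
        if n_tied > 1:
            logger.warning(
                "%s-RFI cut at rfi=%.6g has %d tied birds; resolved by bird_id",
                name,
                boundary,
                n_tied,
            )
    return low.reset_index(drop=True), high.reset_index(drop=True)


def build_pools(
    group: pd.DataFrame,
    n_pools: int,
    pool_size: int,
    sex_balanced: bool = False,
) -> pd.DataFrame:
    """Partition an extreme group into replicate pools matched on phenotype.

    Assignment is a deterministic round-robin over RFI rank (within sex when
    ``sex_balanced``), so each pool receives a comparable spread of RFI
    values. Returns the group with a ``pool`` column (0-based).
    """
    if n_pools * pool_size != len(group):
        raise ValueError(
            f"{n_pools} pools x {pool_size} birds != group size {len(group)}"
        )
    df = group.sort_values(["rfi", "bird_id"], kind="mergesort").reset_index(drop=True)
    if sex_balanced:
        counts = df["sex"].value_counts()
        for sex, cnt in counts.items():
            if cnt % n_pools != 0:
                raise ValueError(
                    f"sex {sex!r} count {cnt} not divisible by {n_pools} pools"
                )
        pool = np.empty(len(df), dtype=int)
        for sex in counts.index:
            idx = df.index[df["sex"] == sex]
            pool[idx] = np.arange(len(idx)) % n_pools
        df["pool"] = pool
    else:
        df["pool"] = np.arange(len(df)) % n_pools
    return df


def group_summary(
    low_group: pd.DataFrame, high_group: pd.DataFrame, traits: list[str] | None = None
) -> pd.DataFrame:
    """Mean +/- SD per trait per group with Student's equal-variance t-test.

    Output columns: trait, low_mean, low_sd, high_mean, high_sd, t, p_value.
    """
    if len(low_group) == 0 or len(high_group) == 0:
        raise ValueError("both groups must be non-empty")
    traits = traits or [t for t in SUMMARY_TRAITS if t in low_group.columns]
    rows = []
    for trait in traits:
        lo = low_group[trait].to_numpy(dtype=float)
        hi = high_group[trait].to_numpy(dtype=float)
        lo = lo[~np.isnan(lo)]
        hi = hi[~np.isnan(hi)]
        t_stat, p = stats.ttest_ind(lo, hi, equal_var=True)
        if np.isnan(p):  # zero variance in both groups and equal means
            t_stat, p = 0.0, 1.0
        rows.append(
            {
                "trait": trait,
                "low_mean": lo.mean(),
                "low_sd": lo.std(ddof=1) if len(lo) > 1 else 0.0,
                "high_mean": hi.mean(),
                "high_sd": hi.std(ddof=1) if len(hi) > 1 else 0.0,
                "t": float(t_stat),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)
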