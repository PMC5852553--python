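"""Pooled-sequencing SNP screen between two phenotypic extreme groups.

Per site: allele frequencies per replicate pool, a one-way ANOVA across
pools with groups as the factor, Benjamini-Hochberg adjustment over sites,
a pooled fixation-index (F_ST) estimate from group-aggregated read counts,
and a three-step candidate filter (q-value cutoff, top-F_ST fraction,
allele-frequency-divergence threshold).

The F_ST estimator is the classical heterozygosity-based pool-seq form: per
group, pi = (C/(C-1)) * 2p(1-p) with C = min(read coverage, sampled
chromosomes), total pi from the combined counts with the same correction,
and F_ST = (pi_T - mean(pi_within)) / pi_T clamped to [0, 1]. A
Karlsson-style count estimator is available as an option.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import BiallelicSite, PoolSpec, SyncSite, reduce_biallelic

__all__ = [
    "ScreenConfig",
    "FilterReport",
    "pool_frequencies",
    "anova_screen",
    "benjamini_hochberg",
    "pooled_fst",
    "karlsson_fst",
    "screen_counts",
    "screen",
    "filter_cascade",
    "per_chromosome_counts",
]


@dataclass
class ScreenConfig:
    """Thresholds and options for the screen and its filter cascade."""

    min_coverage: int = 4
    max_coverage_percentile: float = 99.0
    fst_top_fraction: float = 0.05
    delta_mode: str = "median_of_top"  # or "fixed"
    delta_fixed: float = 0.35
    q_cutoff: float = 0.05
    fst_estimator: str = "pi"  # or "karlsson"
    arcsine: bool = False  # arcsine-sqrt transform frequencies before ANOVA

    def __post_init__(self) -> None:
        if not (0 < self.fst_top_fraction <= 1):
            raise ValueError("fst_top_fraction must be in (0, 1]")
        if not (0 <= self.delta_fixed <= 1):
            raise ValueError("delta_fixed must be in [0, 1]")
        if self.delta_mode not in ("median_of_top", "fixed"):
            raise ValueError(f"unknown delta_mode {self.delta_mode!r}")
        if self.fst_estimator not in ("pi", "karlsson"):
            raise ValueError(f"unknown fst_estimator {self.fst_estimator!r}")


@dataclass
class FilterReport:
    """Counts surviving each filter step plus the realized thresholds."""

    n_input: int = 0
    n_excluded_coverage: int = 0
    n_excluded_triallelic: int = 0
    n_tested: int = 0
    n_after_q: int = 0
    n_after_fst: int = 0
    n_candidates: int = 0
    fst_cutoff: float = float("nan")
    delta_star: float = float("nan")
    delta_mode: str = "median_of_top"
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Per-site operations
# ---------------------------------------------------------------------------


def pool_frequencies(site: BiallelicSite) -> tuple[np.ndarray, np.ndarray]:
    """Alternate-allele frequency and usable coverage per pool."""
    ref = np.asarray(site.ref_counts, dtype=float)
    alt = np.asarray(site.alt_counts, dtype=float)
    cov = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(cov > 0, alt / cov, np.nan)
    return freq, cov


def anova_screen(
    freqs_a: Sequence[float], freqs_b: Sequence[float]
) -> tuple[float, float]:
    """One-way ANOVA F-test of pool frequencies between two groups.

    Observational units are replicate pools; df = (1, n_pools - 2). A fully
    degenerate site (zero between- and within-group variance) returns
    (0.0, 1.0).
    """
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicate pools per group")
    F, p = _anova_arrays(a[None, :], b[None, :])
    return float(F[0]), float(p[0])


def _anova_arrays(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-group one-way ANOVA over rows (sites)."""
    na, nb = a.shape[1], b.shape[1]
    ma = a.mean(axis=1)
    mb = b.mean(axis=1)
    grand = (a.sum(axis=1) + b.sum(axis=1)) / (na + nb)
    ssb = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ssw = ((a - ma[:, None]) ** 2).sum(axis=1) + ((b - mb[:, None]) ** 2).sum(axis=1)
    df1 = 1
    df2 = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    p = np.empty_like(F)
    finite = np.isfinite(F)
    p[finite] = stats.f.sf(F[finite], df1, df2)
    # within-group variance exactly zero: infinite F unless the groups agree
    degenerate = (ssw == 0) & (ssb == 0)
    p[~finite] = 0.0
    F[degenerate] = 0.0
    p[degenerate] = 1.0
    return F, p


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min over j with p_j >= p_i of (m * p_j / rank_j), clamped to 1.
    Invariant to input order; monotone non-decreasing in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def pooled_fst(
    ref_counts: Sequence[int],
    alt_counts: Sequence[int],
    n_chromosomes: Sequence[int],
) -> float:
    """Pool-seq F_ST between two groups from aggregated read counts.

    ``ref_counts``/``alt_counts`` are the per-group reference/alternate read
    counts (replicate pools already summed within group); ``n_chromosomes``
    is the number of sampled chromosomes per group (2 x pooled individuals).
    """
    ref = np.asarray(ref_counts, dtype=float)
    alt = np.asarray(alt_counts, dtype=float)
    chroms = np.asarray(n_chromosomes, dtype=float)
    if ref.shape != (2,) or alt.shape != (2,) or chroms.shape != (2,):
        raise ValueError("pooled_fst compares exactly two groups")
    fst = _fst_arrays(ref[None, :], alt[None, :], chroms)
    return float(fst[0])


def _fst_arrays(
    ref: np.ndarray, alt: np.ndarray, chroms: np.ndarray
) -> np.ndarray:
    """Vectorized pi-based pool F_ST over rows; groups along axis 1."""
    cov = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(cov > 0, alt / cov, 0.0)
    C = np.minimum(cov, chroms[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(C > 1, C / (C - 1.0), 0.0)
    pi_within = corr * 2.0 * p * (1.0 - p)
    ref_t = ref.sum(axis=1)
    alt_t = alt.sum(axis=1)
    cov_t = ref_t + alt_t
    with np.errstate(invalid="ignore", divide="ignore"):
        p_t = np.where(cov_t > 0, alt_t / cov_t, 0.0)
    C_t = np.minimum(cov_t, chroms.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr_t = np.where(C_t > 1, C_t / (C_t - 1.0), 0.0)
    pi_total = corr_t * 2.0 * p_t * (1.0 - p_t)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(
            pi_total > 0, (pi_total - pi_within.mean(axis=1)) / pi_total, 0.0
        )
    return np.clip(fst, 0.0, 1.0)


def karlsson_fst(
    ref_counts: Sequence[int],
    alt_counts: Sequence[int],
) -> float:
    """Karlsson-style count-based F_ST between two groups (optional estimator)."""
    ref = np.asarray(ref_counts, dtype=float)
    alt = np.asarray(alt_counts, dtype=float)
    fst = _karlsson_arrays(ref[None, :], alt[None, :])
    return float(fst[0])


def _karlsson_arrays(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    n = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / n, 0.0)
        h = np.where(n > 1, alt * ref / (n * (n - 1.0)), 0.0)
        num = (p[:, 0] - p[:, 1]) ** 2 - h[:, 0] / n[:, 0] - h[:, 1] / n[:, 1]
    den = num + h[:, 0] + h[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den > 0, num / den, 0.0)
    return np.clip(fst, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Batch screen
# ---------------------------------------------------------------------------


def screen_counts(
    chrom: np.ndarray,
    pos: np.ndarray,
    ref_counts: np.ndarray,
    alt_counts: np.ndarray,
    layout: Sequence[PoolSpec],
    config: ScreenConfig | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run the full screen on count arrays of shape (n_sites, n_pools).

    Returns a per-site result table (coverage-excluded sites dropped) and a
    :class:`FilterReport`. Candidate flags come from :func:`filter_cascade`.
    """
    config = config or ScreenConfig()
    groups = sorted({spec.group for spec in layout})
    if len(groups) != 2:
        raise ValueError(f"screen requires exactly 2 groups, got {groups}")
    ref_counts = np.asarray(ref_counts, dtype=float)
    alt_counts = np.asarray(alt_counts, dtype=float)
    n_sites = ref_counts.shape[0]
    report = FilterReport(n_input=n_sites, delta_mode=config.delta_mode)

    cov = ref_counts + alt_counts
    keep = (cov >= config.min_coverage).all(axis=1)
    if config.max_coverage_percentile < 100 and n_sites > 0:
        caps = np.percentile(cov, config.max_coverage_percentile, axis=0)
        keep &= (cov <= caps[None, :]).all(axis=1)
    report.n_excluded_coverage = int((~keep).sum())

    idx = np.flatnonzero(keep)
    ref_k = ref_counts[idx]
    alt_k = alt_counts[idx]
    cov_k = cov[idx]
    freq = np.where(cov_k > 0, alt_k / cov_k, 0.0)

    cols_a = [i for i, s in enumerate(layout) if s.group == groups[0]]
    cols_b = [i for i, s in enumerate(layout) if s.group == groups[1]]
    fa = freq[:, cols_a]
    fb = freq[:, cols_b]
    if config.arcsine:
        F, p = _anova_arrays(np.arcsin(np.sqrt(fa)), np.arcsin(np.sqrt(fb)))
    else:
        F, p = _anova_arrays(fa, fb)
    q = benjamini_hochberg(p) if len(p) else np.array([])

    ref_g = np.column_stack(
        [ref_k[:, cols_a].sum(axis=1), ref_k[:, cols_b].sum(axis=1)]
    )
    alt_g = np.column_stack(
        [alt_k[:, cols_a].sum(axis=1), alt_k[:, cols_b].sum(axis=1)]
    )
    chroms = np.array(
        [
            sum(2 * layout[i].n_individuals for i in cols_a),
            sum(2 * layout[i].n_individuals for i in cols_b),
        ],
        dtype=float,
    )
    if config.fst_estimator == "karlsson":
        fst = _karlsson_arrays(ref_g, alt_g)
    else:
        fst = _fst_arrays(ref_g, alt_g, chroms)

    p_mean_a = fa.mean(axis=1)
    p_mean_b = fb.mean(axis=1)
    result = pd.DataFrame(
        {
            "chrom": np.asarray(chrom)[idx],
            "pos": np.asarray(pos)[idx],
            f"p_mean_{groups[0]}": p_mean_a,
            f"p_mean_{groups[1]}": p_mean_b,
            "delta_p": np.abs(p_mean_a - p_mean_b),
            "F": F,
            "p_value": p,
            "q_value": q,
            "fst": fst,
        }
    )
    for j, spec in enumerate(layout):
        result[f"freq_{spec.group}_{spec.replicate}"] = freq[:, j]
        result[f"cov_{spec.group}_{spec.replicate}"] = cov_k[:, j]
    result, report = filter_cascade(result, config, report)
    report.n_tested = len(result)
    return result, report


def screen(
    sites: Iterable[SyncSite],
    layout: Sequence[PoolSpec],
    config: ScreenConfig | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run the screen on parsed sync sites (biallelic reduction included)."""
    config = config or ScreenConfig()
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[tuple[int, ...]] = []
    alts: list[tuple[int, ...]] = []
    n_triallelic = 0
    n_input = 0
    for site in sites:
        n_input += 1
        reduced, reason = reduce_biallelic(site)
        if reduced is None:
            n_triallelic += 1
            continue
        chroms.append(reduced.chrom)
        positions.append(reduced.pos)
        refs.append(reduced.ref_counts)
        alts.append(reduced.alt_counts)
    n_pools = len(layout)
    ref_arr = np.array(refs, dtype=float).reshape(-1, n_pools)
    alt_arr = np.array(alts, dtype=float).reshape(-1, n_pools)
    result, report = screen_counts(
        np.array(chroms, dtype=object),
        np.array(positions, dtype=int),
        ref_arr,
        alt_arr,
        layout,
        config,
    )
    report.n_input = n_input
    report.n_excluded_triallelic = n_triallelic
    return result, report


def filter_cascade(
    results: pd.DataFrame,
    config: ScreenConfig | None = None,
    report: FilterReport | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the three-step candidate filter, annotating flag columns.

    Step 1 keeps q_value < q_cutoff; step 2 keeps the top ``fst_top_fraction``
    of the step-1 set by F_ST (boundary ties all retained); step 3 keeps
    delta_p strictly greater than delta* (median delta_p of the step-2 set,
    or the fixed threshold). ``candidate`` requires all three flags.
    """
    config = config or ScreenConfig()
    report = report or FilterReport(n_input=len(results), delta_mode=config.delta_mode)
    df = results.copy()
    df["passed_anova"] = df["q_value"] < config.q_cutoff
    step1 = df[df["passed_anova"]]
    report.n_after_q = len(step1)

    df["in_top5_fst"] = False
    if len(step1) > 0:
        k = max(1, int(np.ceil(config.fst_top_fraction * len(step1))))
        fst_sorted = np.sort(step1["fst"].to_numpy())[::-1]
        cutoff = fst_sorted[k - 1]
        top_mask = df["passed_anova"] & (df["fst"] >= cutoff)
        n_ties_extra = int(top_mask.sum()) - k
        if n_ties_extra > 0:
            report.notes.append(
                f"{n_ties_extra} tie(s) at the F_ST top-fraction boundary retained"
            )
        df.loc[top_mask, "in_top5_fst"] = True
        report.fst_cutoff = float(cutoff)
    else:
        report.notes.append("no SNPs passed the q-value cutoff")
    report.n_after_fst = int(df["in_top5_fst"].sum())

    if config.delta_mode == "fixed":
        delta_star = config.delta_fixed
    else:
        top = df[df["in_top5_fst"]]
        delta_star = float(top["delta_p"].median()) if len(top) else float("nan")
    report.delta_star = delta_star
    if np.isnan(delta_star):
        df["passed_delta"] = False
    else:
        df["passed_delta"] = df["in_top5_fst"] & (df["delta_p"] > delta_star)
    df["candidate"] = df["passed_anova"] & df["in_top5_fst"] & df["passed_delta"]
    report.n_candidates = int(df["candidate"].sum())
    return df, report


def _natural_key(name: str) -> tuple:
    return tuple(
        int(part) if part.isdigit() else part
        for part in re.split(r"(\d+)", str(name))
    )


def per_chromosome_counts(candidates: pd.DataFrame) -> pd.DataFrame:
    """Candidate counts per chromosome, natural-sorted by chromosome name."""
    if len(candidates) == 0:
        return pd.DataFrame(columns=["chrom", "n_candidates"])
    counts = candidates.groupby("chrom").size()
    order = sorted(counts.index, key=_natural_key)
    return pd.DataFrame(
        {"chrom": order, "n_candidates": [int(counts[c]) for c in order]}
    )
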