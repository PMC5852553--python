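"""Bundled reference tables from the original study's validation cohort.

These small TSVs carry published per-SNP association p-values, genotype
least-squares means with printed additive/dominance effects, and group
performance summaries. They serve as fixed inputs for regression tests and
the acceptance report.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_validation_reference",
    "load_genotype_effects_reference",
    "load_group_performance_reference",
    "round_sig",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("poolrfi.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_validation_reference() -> pd.DataFrame:
    """Per-SNP association p-values for the validation cohort (46 SNPs)."""
    return _load("validation_assoc_reference.tsv")


def load_genotype_effects_reference() -> pd.DataFrame:
    """Genotype-class LSMs and printed additive/dominance effects (12 SNPs)."""
    return _load("genotype_effects_reference.tsv")


def load_group_performance_reference() -> pd.DataFrame:
    """Trait means +/- SD for the low/high phenotypic extreme groups."""
    return _load("group_performance_reference.tsv")


def round_sig(x: float, n_digits: int) -> float:
    """Round to ``n_digits`` significant figures."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (n_digits - 1))
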