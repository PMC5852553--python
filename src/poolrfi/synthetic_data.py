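"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is a pure function of its :class:`SimConfig` (the seed is
part of the config), so reruns are bit-identical. Each generator draws from
its own seed stream, so e.g. changing the number of qPCR replicates never
perturbs the pool-count draws.

Generative models:

* phenotypes: FI = b0 + b1*BW^0.75 + b2*WG + a + e, with the additive value
  a following the pedigree (offspring a = mean of parents + Mendelian
  deviation of variance sigma2_a/2; inbreeding ignored);
* pool counts: per locus a base frequency per group, 2 x pool-size allele
  draws per replicate pool, then reads ~ Binomial(coverage, pool frequency)
  with coverage ~ Poisson(mean) truncated at >= 1 — two-stage sampling that
  carries the extra-binomial variance pooled estimators assume;
* validation cohort: Hardy-Weinberg genotypes with planted additive and
  dominance effects, a sex fixed effect and a pedigree-structured polygenic
  term;
* qPCR: normal Ct values with group-specific target means and a shared
  reference-gene mean.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import (
    GeneModel,
    GenotypeTable,
    PedigreeRecord,
    PedigreeTable,
    PoolSpec,
    SyncSite,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PoolSimResult",
    "simulate_phenotypes",
    "simulate_pool_counts",
    "simulate_validation_cohort",
    "simulate_qpcr",
    "toy_gene_models",
]

_NUCS = ("A", "T", "C", "G")


@dataclass
class SimConfig:
    """All knobs for the synthetic generators. ``seed`` is mandatory."""

    seed: int

    # --- discovery phenotypes ---
    n_birds: int = 400
    n_sires: int = 20
    n_dams: int = 40
    true_b0: float = 3.0
    true_b1: float = 2.0
    true_b2: float = 1.5
    sigma2_a: float = 1600.0
    sigma2_e: float = 900.0
    bw_mean: float = 820.0
    bw_sd: float = 100.0
    wg_mean: float = 540.0
    wg_sd: float = 120.0
    test_days: int = 28

    # --- pool counts ---
    n_snps: int = 10_000
    n_divergent: int = 5
    delta_p_planted: float = 0.8
    n_pools_per_group: int = 3
    pool_size: int = 16
    mean_coverage: float = 20.0
    coverage_fixed: Optional[int] = None  # overrides Poisson coverage
    n_sim_chromosomes: int = 5
    group_names: tuple[str, str] = ("LRFI", "HRFI")

    # --- validation cohort ---
    n_validation: int = 800
    val_n_sires: int = 25
    val_n_dams: int = 50
    n_snps_validation: int = 200
    snp_effects: dict = field(default_factory=dict)  # snp index -> (a, d)
    sex_effect: float = 20.0
    val_maf_range: tuple[float, float] = (0.2, 0.8)

    # --- qPCR ---
    qpcr_n_per_group: int = 8
    qpcr_targets: dict = field(default_factory=lambda: {"GENE1": (20.0, 21.0)})
    qpcr_reference_ct: float = 15.0
    qpcr_ct_sd: float = 0.2
    qpcr_groups: tuple[str, str] = ("HRFI", "LRFI")

    def __post_init__(self) -> None:
        if self.sigma2_a < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be >= 0")
        if not (0 <= self.delta_p_planted <= 1):
            raise ValueError("delta_p_planted must be in [0, 1]")
        if self.n_divergent > self.n_snps:
            raise ValueError("n_divergent cannot exceed n_snps")
        if self.pool_size < 1 or self.n_pools_per_group < 1:
            raise ValueError("pools must contain at least one bird")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Everything the generators know that the pipeline must rediscover."""

    true_breeding_values: dict = field(default_factory=dict)
    true_coefficients: Optional[tuple[float, float, float]] = None
    divergent_loci: list = field(default_factory=list)
    locus_group_freqs: dict = field(default_factory=dict)  # snp idx -> (p_low, p_high)
    snp_effects: dict = field(default_factory=dict)  # snp id -> (a, d)
    heritability: Optional[float] = None

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["divergent_loci"] = [int(i) for i in self.divergent_loci]
        payload["locus_group_freqs"] = {
            str(k): [float(v[0]), float(v[1])]
            for k, v in self.locus_group_freqs.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["locus_group_freqs"] = {
            int(k): tuple(v) for k, v in payload["locus_group_freqs"].items()
        }
        payload["snp_effects"] = {
            k: tuple(v) for k, v in payload["snp_effects"].items()
        }
        if payload.get("true_coefficients") is not None:
            payload["true_coefficients"] = tuple(payload["true_coefficients"])
        return cls(**payload)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Mu/sigma of a log-normal with the given arithmetic mean and SD."""
    var = np.log1p((sd / mean) ** 2)
    return np.log(mean) - var / 2.0, np.sqrt(var)


def _founder_pedigree(
    n_sires: int, n_dams: int, n_offspring: int, prefix: str
) -> list[PedigreeRecord]:
    records = [
        PedigreeRecord(f"{prefix}S{i:03d}", None, None, "M") for i in range(n_sires)
    ]
    records += [
        PedigreeRecord(f"{prefix}D{i:03d}", None, None, "F") for i in range(n_dams)
    ]
    for k in range(n_offspring):
        sire = f"{prefix}S{k % n_sires:03d}"
        dam = f"{prefix}D{k % n_dams:03d}"
        sex = "M" if k % 2 == 0 else "F"
        records.append(PedigreeRecord(f"{prefix}B{k:04d}", sire, dam, sex))
    return records


def _breeding_values(
    pedigree: PedigreeTable, sigma2_a: float, rng: np.random.Generator
) -> dict[str, float]:
    """Recursive additive values: founders N(0, s2a), offspring mid-parent
    plus a Mendelian deviation of variance s2a/2 (inbreeding ignored)."""
    bv: dict[str, float] = {}
    by_id = {r.animal_id: r for r in pedigree.records}
    sd_founder = np.sqrt(sigma2_a)
    sd_mendel = np.sqrt(sigma2_a / 2.0)
    for animal in pedigree.topological_order():
        rec = by_id[animal]
        if rec.sire_id is None and rec.dam_id is None:
            bv[animal] = float(rng.normal(0.0, sd_founder))
        else:
            mid = 0.5 * bv.get(rec.sire_id, 0.0) + 0.5 * bv.get(rec.dam_id, 0.0)
            bv[animal] = float(mid + rng.normal(0.0, sd_mendel))
    return bv


# ---------------------------------------------------------------------------
# Discovery phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    config: SimConfig,
) -> tuple[pd.DataFrame, PedigreeTable, GroundTruth]:
    """Simulate the discovery population's intake phenotypes.

    Returns (phenotype table, pedigree incl. founders, ground truth). Feed
    intake is the exact regression plus the bird's additive value and a
    residual; founders carry no phenotype records.
    """
    rng = config.rng(1)
    pedigree = PedigreeTable(
        _founder_pedigree(config.n_sires, config.n_dams, config.n_birds, "Y")
    )
    bv = _breeding_values(pedigree, config.sigma2_a, rng)
    birds = [r for r in pedigree.records if r.sire_id is not None]
    n = len(birds)
    mu_bw, sd_bw = _lognormal_params(config.bw_mean, config.bw_sd)
    mu_wg, sd_wg = _lognormal_params(config.wg_mean, config.wg_sd)
    initial_bw = rng.lognormal(mu_bw, sd_bw, size=n)
    wg = rng.lognormal(mu_wg, sd_wg, size=n)
    e = (
        rng.normal(0.0, np.sqrt(config.sigma2_e), size=n)
        if config.sigma2_e > 0
        else np.zeros(n)
    )
    a = np.array([bv[b.animal_id] for b in birds])
    mbw = initial_bw**0.75
    total_fi = config.true_b0 + config.true_b1 * mbw + config.true_b2 * wg + a + e
    table = pd.DataFrame(
        {
            "bird_id": [b.animal_id for b in birds],
            "sex": [b.sex for b in birds],
            "sire_id": [b.sire_id for b in birds],
            "dam_id": [b.dam_id for b in birds],
            "initial_bw": initial_bw,
            "final_bw": initial_bw + wg,
            "total_fi": total_fi,
            "test_days": config.test_days,
        }
    )
    truth = GroundTruth(
        true_breeding_values=bv,
        true_coefficients=(config.true_b0, config.true_b1, config.true_b2),
        heritability=(
            config.sigma2_a / (config.sigma2_a + config.sigma2_e)
            if config.sigma2_a + config.sigma2_e > 0
            else None
        ),
    )
    return table, pedigree, truth


# ---------------------------------------------------------------------------
# Pool counts
# ---------------------------------------------------------------------------


@dataclass
class PoolSimResult:
    """Array-form pooled counts plus layout; convertible to sync sites."""

    chrom: np.ndarray
    pos: np.ndarray
    ref_base: np.ndarray
    alt_base: np.ndarray
    ref_counts: np.ndarray  # (n_sites, n_pools)
    alt_counts: np.ndarray
    layout: list[PoolSpec]
    truth: GroundTruth
    group_freqs: np.ndarray | None = None  # (n_sites, 2) generating frequencies

    def to_sync_sites(self) -> list[SyncSite]:
        sites = []
        base_idx = {b: i for i, b in enumerate(_NUCS)}
        for i in range(len(self.pos)):
            counts = []
            for j in range(len(self.layout)):
                tup = [0, 0, 0, 0, 0, 0]
                tup[base_idx[self.ref_base[i]]] = int(self.ref_counts[i, j])
                tup[base_idx[self.alt_base[i]]] = int(self.alt_counts[i, j])
                counts.append(tuple(tup))
            sites.append(
                SyncSite(str(self.chrom[i]), int(self.pos[i]), str(self.ref_base[i]), tuple(counts))
            )
        return sites


def simulate_pool_counts(config: SimConfig) -> PoolSimResult:
    """Simulate pooled read counts for two groups of replicate pools.

    Divergent loci get group base frequencies separated by exactly
    ``delta_p_planted``; all other loci share one frequency. Each replicate
    pool draws 2 x pool_size chromosomes from its group frequency, then
    reads binomially at Poisson coverage (truncated at >= 1).
    """
    rng = config.rng(2)
    n = config.n_snps
    n_pools = 2 * config.n_pools_per_group
    layout = [
        PoolSpec(group, rep, config.pool_size)
        for group in config.group_names
        for rep in range(config.n_pools_per_group)
    ]
    base_p = rng.uniform(0.1, 0.9, size=n)
    divergent = np.sort(rng.choice(n, size=config.n_divergent, replace=False))
    delta = config.delta_p_planted
    p_low = base_p.copy()
    p_high = base_p.copy()
    centers = np.clip(base_p[divergent], delta / 2, 1 - delta / 2)
    p_low[divergent] = centers - delta / 2
    p_high[divergent] = centers + delta / 2
    group_p = {config.group_names[0]: p_low, config.group_names[1]: p_high}

    n_chrom_pool = 2 * config.pool_size
    ref_counts = np.empty((n, n_pools), dtype=np.int64)
    alt_counts = np.empty((n, n_pools), dtype=np.int64)
    for j, spec in enumerate(layout):
        pool_alt_chroms = rng.binomial(n_chrom_pool, group_p[spec.group])
        pool_freq = pool_alt_chroms / n_chrom_pool
        if config.coverage_fixed is not None:
            coverage = np.full(n, config.coverage_fixed, dtype=np.int64)
        else:
            coverage = np.maximum(1, rng.poisson(config.mean_coverage, size=n))
        alt = rng.binomial(coverage, pool_freq)
        alt_counts[:, j] = alt
        ref_counts[:, j] = coverage - alt

    loci_per_chrom = int(np.ceil(n / config.n_sim_chromosomes))
    chrom = np.array(
        [f"chr{i // loci_per_chrom + 1}" for i in range(n)], dtype=object
    )
    pos = np.array([(i % loci_per_chrom + 1) * 1000 for i in range(n)], dtype=int)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    nucs = np.array(_NUCS, dtype=object)
    truth = GroundTruth(
        divergent_loci=list(map(int, divergent)),
        locus_group_freqs={
            int(i): (float(p_low[i]), float(p_high[i])) for i in divergent
        },
    )
    return PoolSimResult(
        chrom=chrom,
        pos=pos,
        ref_base=nucs[ref_idx],
        alt_base=nucs[alt_idx],
        ref_counts=ref_counts,
        alt_counts=alt_counts,
        layout=layout,
        truth=truth,
        group_freqs=np.column_stack([p_low, p_high]),
    )


# ---------------------------------------------------------------------------
# Validation cohort
# ---------------------------------------------------------------------------


def simulate_validation_cohort(
    config: SimConfig,
) -> tuple[GenotypeTable, pd.DataFrame, PedigreeTable, GroundTruth]:
    """Simulate the independent validation population.

    Genotypes are Hardy-Weinberg at per-SNP frequencies; phenotypes add the
    planted SNP effects (+a per alt dosage step from the heterozygote, +d
    for heterozygotes), a sex fixed effect, a pedigree additive value and a
    residual. Only offspring carry phenotype records.
    """
    rng = config.rng(3)
    pedigree = PedigreeTable(
        _founder_pedigree(config.val_n_sires, config.val_n_dams, config.n_validation, "V")
    )
    bv = _breeding_values(pedigree, config.sigma2_a, rng)
    birds = [r for r in pedigree.records if r.sire_id is not None]
    n = len(birds)
    m = config.n_snps_validation
    freqs = rng.uniform(*config.val_maf_range, size=m)
    for idx in config.snp_effects:
        if not (0 < freqs[int(idx)] < 1):
            raise ValueError(f"effect SNP {idx} has degenerate frequency")
    dosage = rng.binomial(2, freqs, size=(n, m)).astype(float)

    snp_ids = [f"snp{i:05d}" for i in range(m)]
    effects = np.zeros(n)
    truth_effects: dict[str, tuple[float, float]] = {}
    for idx, (a_eff, d_eff) in config.snp_effects.items():
        g = dosage[:, int(idx)]
        effects += a_eff * (g - 1.0) + d_eff * (g == 1.0)
        truth_effects[snp_ids[int(idx)]] = (float(a_eff), float(d_eff))

    sexes = np.array([b.sex for b in birds], dtype=object)
    e = (
        rng.normal(0.0, np.sqrt(config.sigma2_e), size=n)
        if config.sigma2_e > 0
        else np.zeros(n)
    )
    a = np.array([bv[b.animal_id] for b in birds])
    y = config.sex_effect * (sexes == "M").astype(float) + effects + a + e

    pheno = pd.DataFrame(
        {
            "bird_id": [b.animal_id for b in birds],
            "sex": sexes,
            "sire_id": [b.sire_id for b in birds],
            "dam_id": [b.dam_id for b in birds],
            "rfi": y,
        }
    )
    ref = np.full(m, "A", dtype=object)
    alt = np.full(m, "G", dtype=object)
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * m,
            "pos": [(i + 1) * 500 for i in range(m)],
            "id": snp_ids,
            "ref": ref,
            "alt": alt,
        }
    )
    table = GenotypeTable(
        dosage=pd.DataFrame(dosage, index=[b.animal_id for b in birds], columns=snp_ids),
        sites=sites,
    )
    truth = GroundTruth(
        true_breeding_values=bv,
        snp_effects=truth_effects,
        heritability=(
            config.sigma2_a / (config.sigma2_a + config.sigma2_e)
            if config.sigma2_a + config.sigma2_e > 0
            else None
        ),
    )
    return table, pheno, pedigree, truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def simulate_qpcr(config: SimConfig) -> pd.DataFrame:
    """Two-group Ct table; reference-gene group means are equal by design."""
    rng = config.rng(4)
    rows = []
    g1, g2 = config.qpcr_groups
    for gene, (mean1, mean2) in config.qpcr_targets.items():
        for group, target_mean in ((g1, mean1), (g2, mean2)):
            for k in range(config.qpcr_n_per_group):
                rows.append(
                    {
                        "sample_id": f"{group}_{gene}_{k}",
                        "group": group,
                        "gene": gene,
                        "ct_target": float(rng.normal(target_mean, config.qpcr_ct_sd)),
                        "ct_reference": float(
                            rng.normal(config.qpcr_reference_ct, config.qpcr_ct_sd)
                        ),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Toy gene set
# ---------------------------------------------------------------------------


def toy_gene_models(config: SimConfig, spacing: int = 200_000) -> list[GeneModel]:
    """A deterministic toy gene set spanning the simulated chromosomes."""
    loci_per_chrom = int(np.ceil(config.n_snps / config.n_sim_chromosomes))
    span = max(loci_per_chrom * 1000, spacing)
    genes = []
    for c in range(1, config.n_sim_chromosomes + 1):
        g = 0
        for start in range(10_000, span, spacing):
            end = start + 60_000
            cds = ((start + 5_000, start + 5_299, 0),)
            exons = ((start + 5_000, start + 5_299),)
            genes.append(
                GeneModel(
                    gene_id=f"gene_c{c}_{g}",
                    chrom=f"chr{c}",
                    start=start,
                    end=end,
                    strand="+" if g % 2 == 0 else "-",
                    cds_intervals=cds,
                    exon_intervals=exons,
                )
            )
            g += 1
    return genes
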