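"""Readers and writers for the external formats used by the pipeline.

All genomic coordinates are 1-based inclusive, matching the serialized
conventions of the sync, GFF3 and VCF formats. Parsers validate eagerly and
raise :class:`FormatError` with a line number where possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "PedigreeError",
    "SyncSite",
    "BiallelicSite",
    "PoolSpec",
    "GeneModel",
    "PedigreeRecord",
    "PedigreeTable",
    "GenotypeTable",
    "read_sync",
    "write_sync",
    "reduce_biallelic",
    "read_gff3_genes",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "read_phenotypes_csv",
    "write_phenotypes_csv",
    "read_results_table",
    "write_results_table",
]

#: Base order of the colon-separated count fields in a sync column.
SYNC_BASES = ("A", "T", "C", "G", "N", "del")
_NUCS = ("A", "T", "C", "G")


class FormatError(ValueError):
    """A file violated its format contract."""


class PedigreeError(ValueError):
    """A pedigree violated a structural invariant (cycle, duplicate id...)."""


@dataclass(frozen=True)
class PoolSpec:
    """Identity of one sync column: phenotypic group, replicate, pool size."""

    group: str
    replicate: int
    n_individuals: int = 16


@dataclass(frozen=True)
class SyncSite:
    """One biallelic-candidate site with raw base counts per pool.

    ``counts_per_pool`` holds one ``(A, T, C, G, N, del)`` tuple per pool
    column, in file order.
    """

    chrom: str
    pos: int
    ref: str
    counts_per_pool: tuple[tuple[int, int, int, int, int, int], ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        for counts in self.counts_per_pool:
            if len(counts) != 6:
                raise FormatError("each pool needs 6 count fields (A:T:C:G:N:del)")
            if any(c < 0 for c in counts):
                raise FormatError(f"negative count at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class BiallelicSite:
    """A sync site reduced to a reference/alternate allele pair."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ref_counts: tuple[int, ...]
    alt_counts: tuple[int, ...]


def read_sync(path: str | Path, pool_labels: Sequence[PoolSpec]) -> list[SyncSite]:
    """Parse a PoPoolation2-style sync file.

    Each data line is ``chrom<TAB>pos<TAB>ref`` followed by one
    ``A:T:C:G:N:del`` column per pool. ``pool_labels`` declares the expected
    pool layout; a column-count mismatch is a :class:`FormatError` naming the
    offending line.
    """
    n_pools = len(pool_labels)
    sites: list[SyncSite] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + n_pools:
                raise FormatError(
                    f"{path}: line {lineno}: expected {3 + n_pools} columns "
                    f"({n_pools} pools), found {len(fields)}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: bad position {pos_s!r}") from exc
            counts = []
            for col in fields[3:]:
                parts = col.split(":")
                if len(parts) != 6:
                    raise FormatError(
                        f"{path}: line {lineno}: pool column {col!r} is not A:T:C:G:N:del"
                    )
                try:
                    tup = tuple(int(p) for p in parts)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: non-integer count in {col!r}"
                    ) from exc
                if any(c < 0 for c in tup):
                    raise FormatError(f"{path}: line {lineno}: negative count in {col!r}")
                counts.append(tup)
            try:
                sites.append(SyncSite(chrom, pos, ref, tuple(counts)))
            except FormatError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return sites


def write_sync(sites: Iterable[SyncSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for site in sites:
            cols = "\t".join(":".join(str(c) for c in tup) for tup in site.counts_per_pool)
            fh.write(f"{site.chrom}\t{site.pos}\t{site.ref}\t{cols}\n")


def reduce_biallelic(
    site: SyncSite, max_third_allele_frac: float = 0.05
) -> tuple[Optional[BiallelicSite], Optional[str]]:
    """Collapse a sync site to its reference/alternate allele pair.

    The alternate allele is the most frequent non-reference nucleotide summed
    over all pools (ties broken by base order A,T,C,G). Sites where the
    remaining third/fourth alleles exceed ``max_third_allele_frac`` of total
    nucleotide reads are excluded. Returns ``(site, None)`` on success or
    ``(None, reason)`` on exclusion. N and deletion counts are ignored.
    """
    ref = site.ref.upper()
    if ref not in _NUCS:
        return None, "ref_not_nucleotide"
    totals = {b: 0 for b in _NUCS}
    for counts in site.counts_per_pool:
        for i, b in enumerate(_NUCS):
            totals[b] += counts[i]
    grand_total = sum(totals.values())
    if grand_total == 0:
        return None, "no_reads"
    non_ref = [b for b in _NUCS if b != ref]
    alt = max(non_ref, key=lambda b: (totals[b], -non_ref.index(b)))
    third = sum(totals[b] for b in non_ref if b != alt)
    if third > max_third_allele_frac * grand_total:
        return None, "third_allele"
    iref, ialt = _NUCS.index(ref), _NUCS.index(alt)
    ref_counts = tuple(c[iref] for c in site.counts_per_pool)
    alt_counts = tuple(c[ialt] for c in site.counts_per_pool)
    return (
        BiallelicSite(site.chrom, site.pos, ref, alt, ref_counts, alt_counts),
        None,
    )


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene with its genomic span and CDS/exon structure.

    Intervals are 1-based inclusive and stored in genomic coordinate order
    regardless of strand; ``strand`` records transcription direction.
    ``cds_intervals`` items are ``(start, end, phase)``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_intervals: tuple[tuple[int, int, int], ...] = ()
    exon_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = None
        for s, e, _ in self.cds_intervals:
            if s < self.start or e > self.end:
                raise FormatError(f"gene {self.gene_id}: CDS [{s},{e}] outside gene span")
            if prev_end is not None and s <= prev_end:
                raise FormatError(f"gene {self.gene_id}: CDS intervals overlap or unsorted")
            prev_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds_intervals)


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as minimal GFF3 (gene/mRNA/exon/CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\t.\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for s, e in g.exon_intervals:
                fh.write(
                    f"{g.chrom}\t.\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={mrna_id}\n"
                )
            for s, e, phase in g.cds_intervals:
                fh.write(
                    f"{g.chrom}\t.\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"Parent={mrna_id}\n"
                )


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Load gene models from a GFF3 file.

    One :class:`GeneModel` per ``gene`` feature. When a gene carries several
    transcripts the one with the longest total CDS is used. Genes are returned
    sorted by (chrom, start).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript"), level=1))
        candidates = transcripts if transcripts else [gene]
        best_cds: list = []
        best_exons: list = []
        for parent in candidates:
            cds = sorted(
                db.children(parent, featuretype="CDS"), key=lambda f: f.start
            )
            exons = sorted(
                db.children(parent, featuretype="exon"), key=lambda f: f.start
            )
            if sum(f.end - f.start + 1 for f in cds) >= sum(
                f.end - f.start + 1 for f in best_cds
            ):
                best_cds, best_exons = cds, exons
        cds_tuples = tuple(
            (f.start, f.end, int(f.frame) if f.frame not in (None, ".") else 0)
            for f in best_cds
        )
        exon_tuples = tuple((f.start, f.end) for f in best_exons)
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                cds_intervals=cds_tuples,
                exon_intervals=exon_tuples,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Alternate-allele dosage matrix (samples x sites) plus site metadata.

    ``dosage`` holds 0/1/2 with NaN for missing calls. ``sites`` has one row
    per retained column with chrom, pos, id, ref, alt.
    """

    dosage: pd.DataFrame
    sites: pd.DataFrame
    n_skipped_multiallelic: int = 0


def read_genotypes_vcf(path: str | Path) -> GenotypeTable:
    """Read biallelic GT dosages from a VCF.

    Multi-allelic sites are skipped with a warning and counted on the result.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    columns: list[str] = []
    rows: list[dict] = []
    dosages: list[np.ndarray] = []
    skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            skipped += 1
            continue
        # gts012=True: 0/1/2 = alt dosage, 3 = missing
        gt = variant.gt_types.astype(float)
        gt[gt == 3] = np.nan
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        columns.append(snp_id)
        rows.append(
            {
                "chrom": variant.CHROM,
                "pos": variant.POS,
                "id": snp_id,
                "ref": variant.REF,
                "alt": variant.ALT[0],
            }
        )
        dosages.append(gt)
    vcf.close()
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} multi-allelic site(s)", stacklevel=2)
    mat = (
        np.column_stack(dosages) if dosages else np.empty((len(samples), 0))
    )
    dosage = pd.DataFrame(mat, index=samples, columns=columns)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypeTable(dosage=dosage, sites=sites, n_skipped_multiallelic=skipped)


def write_genotypes_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT fields from a dosage table."""
    gt_strings = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(str(s) for s in table.dosage.index)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for _, site in table.sites.iterrows():
            col = table.dosage[site["id"]]
            gts = "\t".join(
                "./." if np.isnan(v) else gt_strings[float(v)] for v in col
            )
            fh.write(
                f"{site['chrom']}\t{site['pos']}\t{site['id']}\t{site['ref']}\t"
                f"{site['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedigreeRecord:
    animal_id: str
    sire_id: Optional[str]
    dam_id: Optional[str]
    sex: str


@dataclass
class PedigreeTable:
    """Validated pedigree: unique ids, known parents, no cycles."""

    records: list[PedigreeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.animal_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate animal ids: {dupes[:5]}")
        known = set(ids)
        for r in self.records:
            for parent in (r.sire_id, r.dam_id):
                if parent is not None and parent not in known:
                    raise PedigreeError(
                        f"animal {r.animal_id}: unknown parent {parent!r}"
                    )
        self.topological_order()  # raises on cycles

    def __len__(self) -> int:
        return len(self.records)

    def topological_order(self) -> list[str]:
        """Animal ids ordered parents-before-offspring; cycles are errors."""
        by_id = {r.animal_id: r for r in self.records}
        order: list[str] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for root in by_id:
            if root in state:
                continue
            stack: list[tuple[str, bool]] = [(root, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    state[node] = 1
                    order.append(node)
                    continue
                if state.get(node) == 1:
                    continue
                if state.get(node) == 0:
                    raise PedigreeError(f"pedigree cycle involving animal {node!r}")
                state[node] = 0
                stack.append((node, True))
                rec = by_id[node]
                for parent in (rec.sire_id, rec.dam_id):
                    if parent is not None and state.get(parent) != 1:
                        if state.get(parent) == 0:
                            raise PedigreeError(
                                f"pedigree cycle involving animal {parent!r}"
                            )
                        stack.append((parent, False))
        return order

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": [r.animal_id for r in self.records],
                "sire": [r.sire_id or "0" for r in self.records],
                "dam": [r.dam_id or "0" for r in self.records],
                "sex": [r.sex for r in self.records],
            }
        )


def read_pedigree_csv(path: str | Path) -> PedigreeTable:
    """Read a pedigree CSV with columns animal,sire,dam,sex ('0' = unknown)."""
    df = pd.read_csv(path, dtype=str)
    required = {"animal", "sire", "dam", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing pedigree columns {sorted(missing)}")
    records = [
        PedigreeRecord(
            animal_id=row.animal,
            sire_id=None if row.sire in ("0", "", None) else row.sire,
            dam_id=None if row.dam in ("0", "", None) else row.dam,
            sex=row.sex,
        )
        for row in df.itertuples()
    ]
    return PedigreeTable(records)


def write_pedigree_csv(pedigree: PedigreeTable, path: str | Path) -> None:
    pedigree.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Phenotypes and generic result tables
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = [
    "bird_id",
    "sex",
    "sire_id",
    "dam_id",
    "initial_bw",
    "final_bw",
    "total_fi",
    "test_days",
]


def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"bird_id": str, "sire_id": str, "dam_id": str})
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing phenotype columns {sorted(missing)}")
    return df


def write_phenotypes_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_results_table(
    records: pd.DataFrame,
    path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    """Write a results DataFrame as TSV, with optional '#' comment header.

    String cells containing tabs or newlines are rejected so the file
    round-trips losslessly through :func:`read_results_table`.
    """
    for col in records.columns:
        if records[col].dtype == object:
            bad = records[col].astype(str).str.contains("[\t\n]", regex=True)
            if bad.any():
                raise FormatError(
                    f"column {col!r} contains tab/newline characters; refusing to write"
                )
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        records.to_csv(fh, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
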