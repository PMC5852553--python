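"""Gene assignment within a +/-50 kb window and SNP consequence categories.

A SNP is assigned to every gene whose span lies within ``window`` bp of it
(inclusive at exactly ``window``). Each SNP receives exactly one category
with precedence CDS > intron > upstream/downstream (nearest gene wins);
coding changes are classified against the standard genetic code with
strand-aware codon construction.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .io_formats import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "SnpAnnotation",
    "assign_genes",
    "categorize_snp",
    "annotation_summary",
    "annotate_candidates",
]

CATEGORIES = (
    "intergenic",
    "upstream",
    "downstream",
    "intron",
    "exon_synonymous",
    "exon_missense",
    "exon_other",
)

DEFAULT_WINDOW = 50_000


@dataclass(frozen=True)
class SnpAnnotation:
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    category: str
    gene_ids: tuple[str, ...]
    distance: int  # bp to the nearest assigned gene, 0 if inside


def _gene_distance(gene: GeneModel, pos: int) -> int:
    if gene.start <= pos <= gene.end:
        return 0
    return gene.start - pos if pos < gene.start else pos - gene.end


def assign_genes(
    chrom: str,
    pos: int,
    gene_models: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW,
) -> list[tuple[str, int]]:
    """All genes whose span is within ``window`` bp of the SNP, with distances.

    Inclusive boundary: a gap of exactly ``window`` bp still assigns. Result
    is sorted by (distance, gene_id).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    hits = [
        (g.gene_id, _gene_distance(g, pos))
        for g in gene_models
        if g.chrom == chrom and _gene_distance(g, pos) <= window
    ]
    hits.sort(key=lambda t: (t[1], t[0]))
    return hits


def _cds_codon(
    gene: GeneModel, pos: int, ref_allele: str, alt_allele: str,
    sequences: Mapping[str, object],
) -> tuple[str, str] | None:
    """Reference and mutated codon covering ``pos``, or None if unresolvable."""
    seq = sequences.get(gene.chrom)
    if seq is None:
        return None
    # coding sequence in transcription order
    parts = []
    for s, e, _ in gene.cds_intervals:
        parts.append(str(seq[s - 1 : e]).upper())
    if gene.strand == "+":
        cds = "".join(parts)
        offset = 0
        for s, e, _ in gene.cds_intervals:
            if s <= pos <= e:
                offset += pos - s
                break
            offset += e - s + 1
        phase = gene.cds_intervals[0][2]
        snp_base, snp_alt = ref_allele.upper(), alt_allele.upper()
    else:
        cds = str(Seq("".join(parts)).reverse_complement())
        offset = 0
        for s, e, _ in reversed(gene.cds_intervals):
            if s <= pos <= e:
                offset += e - pos
                break
            offset += e - s + 1
        phase = gene.cds_intervals[-1][2]
        snp_base = str(Seq(ref_allele.upper()).complement())
        snp_alt = str(Seq(alt_allele.upper()).complement())
    offset -= phase
    if offset < 0:
        return None
    cds = cds[phase:]
    codon_start = (offset // 3) * 3
    codon = cds[codon_start : codon_start + 3]
    if len(codon) != 3:
        return None
    within = offset % 3
    if codon[within] != snp_base:
        logger.warning(
            "reference mismatch at %s:%d (gene %s): codon has %s, allele %s",
            gene.chrom, pos, gene.gene_id, codon[within], snp_base,
        )
    mutated = codon[:within] + snp_alt + codon[within + 1 :]
    return codon, mutated


def categorize_snp(
    chrom: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
    gene_models: Sequence[GeneModel],
    sequences: Mapping[str, object] | None = None,
    window: int = DEFAULT_WINDOW,
) -> SnpAnnotation:
    """Categorize one SNP against the gene set.

    ``sequences`` maps chromosome name to an indexable reference sequence
    (a string or a pyfaidx record); without it, coding SNPs fall back to
    ``exon_other``.
    """
    by_id = {g.gene_id: g for g in gene_models if g.chrom == chrom}
    hits = assign_genes(chrom, pos, gene_models, window)
    gene_ids = tuple(gid for gid, _ in hits)
    if not hits:
        return SnpAnnotation(chrom, pos, ref_allele, alt_allele, "intergenic", (), -1)

    inside = [by_id[gid] for gid, d in hits if d == 0]
    # CDS has top precedence
    for gene in inside:
        for s, e, _ in gene.cds_intervals:
            if s <= pos <= e:
                category = "exon_other"
                if sequences is not None and gene.cds_length % 3 == 0:
                    codons = _cds_codon(gene, pos, ref_allele, alt_allele, sequences)
                    if codons is not None:
                        ref_aa = str(Seq(codons[0]).translate())
                        alt_aa = str(Seq(codons[1]).translate())
                        category = (
                            "exon_synonymous" if ref_aa == alt_aa else "exon_missense"
                        )
                return SnpAnnotation(
                    chrom, pos, ref_allele, alt_allele, category, gene_ids, 0
                )
    # non-coding exon (e.g. UTR), then intron
    for gene in inside:
        for s, e in gene.exon_intervals:
            if s <= pos <= e:
                return SnpAnnotation(
                    chrom, pos, ref_allele, alt_allele, "exon_other", gene_ids, 0
                )
    if inside:
        return SnpAnnotation(chrom, pos, ref_allele, alt_allele, "intron", gene_ids, 0)

    # outside all spans: upstream/downstream of the nearest gene
    nearest_id, distance = hits[0]
    gene = by_id[nearest_id]
    five_prime_side = pos < gene.start if gene.strand == "+" else pos > gene.end
    category = "upstream" if five_prime_side else "downstream"
    return SnpAnnotation(chrom, pos, ref_allele, alt_allele, category, gene_ids, distance)


def annotation_summary(annotations: Sequence[SnpAnnotation]) -> pd.DataFrame:
    """Counts per category (all categories present, zeros included)."""
    counts = Counter(a.category for a in annotations)
    return pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "n_snps": [counts.get(c, 0) for c in CATEGORIES],
        }
    )


def annotate_candidates(
    candidates: pd.DataFrame,
    gene_models: Sequence[GeneModel],
    sequences: Mapping[str, object] | None = None,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Annotate a candidate table (chrom, pos[, ref_allele, alt_allele])."""
    missing_chroms: set[str] = set()
    known_chroms = {g.chrom for g in gene_models}
    rows = []
    for rec in candidates.itertuples():
        chrom = str(rec.chrom)
        if chrom not in known_chroms and chrom not in missing_chroms:
            missing_chroms.add(chrom)
            logger.warning("chromosome %s absent from the gene set", chrom)
        ann = categorize_snp(
            chrom,
            int(rec.pos),
            getattr(rec, "ref_allele", "N"),
            getattr(rec, "alt_allele", "N"),
            gene_models,
            sequences,
            window,
        )
        rows.append(
            {
                "chrom": ann.chrom,
                "pos": ann.pos,
                "category": ann.category,
                "gene_ids": ",".join(ann.gene_ids),
                "distance": ann.distance,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "category", "gene_ids", "distance"]
    )
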