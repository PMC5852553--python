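# poolrfi

A reusable pipeline for finding genomic variants associated with residual
feed intake (RFI) in chickens from pooled whole-genome sequencing, with
validation in an independent pedigreed population.

Stages:

1. **Phenotype** (`phenotype_rfi`) — RFI as the residual of an OLS fit of
   feed intake on metabolic body weight (BW^0.75) and weight gain; selection
   of phenotypic extremes and construction of replicate sequencing pools;
   group summaries with Student's t-tests (incl. feed conversion ratio).
2. **Pool screen** (`pool_screen`) — per-SNP allele frequencies from
   PoPoolation2-style sync counts, replicate ANOVA with Benjamini–Hochberg
   adjustment, pooled F_ST between the extreme groups, and a three-step
   candidate filter (q < 0.05, top-5% F_ST, allele-frequency divergence
   above the median of the top set or a fixed 35%).
3. **Annotation** (`gene_annotation`) — gene assignment within ±50 kb
   (inclusive) and SNP categorization (intergenic / upstream / downstream /
   intron / synonymous / missense / other) with strand-aware codons.
4. **Validation** (`validation_assoc`) — pedigree relationship matrix
   (tabular method), animal-model BLUP breeding values (with EM-REML
   variance components or a fixed h²), per-SNP Wald tests of EBV on dosage,
   genotype least-squares means, and additive/dominance decomposition.
5. **Expression** (`expression_qpcr`) — 2^−ΔΔCt relative expression with
   Student's t-test on ΔCt.

A synthetic-data module (`synthetic_data`) generates every input with known
ground truth, so the full pipeline runs and is testable without any
external data. Small published reference tables (genotype least-squares
means, association p-values, group performance) are bundled under
`poolrfi/data/` for regression tests and the acceptance report.

## Tests

```sh
python -m pytest -q tests/
```

One acceptance test is deliberately red:
`TestCriterion4aScreenPower`. With 3 replicate pools per group the per-SNP
ANOVA has df (1, 4); at ~20× coverage planted loci with an allele-frequency
difference of 0.8 reach p ≈ 1e-4, while Benjamini–Hochberg across ~10,000
loci needs p < ~3e-5 — so near-certain recovery of all planted loci at
genome scale is not achievable with this screen design. The test implements
the stated target faithfully and documents the shortfall rather than
weakening it.

## CLI

```sh
poolrfi run --outdir demo_run --seed 1          # bundled synthetic demo
poolrfi run --config run.yaml                   # or from a YAML config
poolrfi simulate --out datadir --seed 1
poolrfi phenotype --pheno pheno.csv --out rfi.tsv --n-extreme 48 --pools 3 --pool-size 16
poolrfi screen --sync pools.sync --layout layout.yaml --out screen.tsv [--delta fixed:0.35]
poolrfi annotate --candidates screen.tsv --gff genes.gff3 --window 50000 --out annot.tsv
poolrfi validate --vcf geno.vcf --pheno pheno.csv --ped pedigree.csv --out assoc.tsv [--h2 0.3 | --reml]
poolrfi qpcr --ct ct.csv --reference-group HRFI --out expr.tsv
```

The `screen` layout YAML lists one entry per sync column:
`[{group: LRFI, replicate: 0, n_individuals: 16}, ...]`.

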