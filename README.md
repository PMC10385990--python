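# sigmeta

Cross-species transcriptome **sig**nature **meta**-analysis: a tested,
reusable pipeline that turns per-contrast differential expression into
signed significance signatures, maps them into a common reference gene
space, and integrates evidence across many contrasts and species — at the
gene level, the pathway level and the predicted-metabolite level.

## What it does

1. **Differential expression & signatures** (`sigmeta.designature`) —
   per-contrast two-group DE (library-size normalization + moderated
   t-test, or externally supplied DE tables), transformed into the
   signature `s = -log10(p) * sign(log FC)`.
2. **Ortholog mapping** (`sigmeta.orthomap`) — conversion of species-level
   signatures to reference gene identifiers via confidence-scored ortholog
   tables, reciprocal best hits from BLAST-tabular files, or two-hop
   composition of both.
3. **Correlation analysis** (`sigmeta.simmatrix`) — pairwise-complete
   Pearson correlation between contrast signatures with t-based p-values.
4. **Gene-level integration** (`sigmeta.integrate`) — species-balanced
   weighted Stouffer Z (`Z = sum(w z) / sqrt(sum(w^2))`, one unit of weight
   per species), two-tailed p, BH FDR, a ≥k-species presence filter, and
   classification of conserved responders by integrated Z and
   cross-contrast signature SD.
5. **Pathway enrichment** (`sigmeta.enrich`) — permutation GSEA (weighted
   KS running sum, gene-label permutation null, sign-conditional NES) per
   contrast, then Stouffer integration of NES across contrasts.
6. **Metabolite prediction** (`sigmeta.metabopredict`) — Spearman
   gene–metabolite models fit on a paired transcriptome/metabolome
   reference, applied to contrast signatures as a calibrated difference of
   positive-set and negative-set enrichment.
7. **Synthetic data** (`sigmeta.simulate`) — negative-binomial
   multi-species studies with planted conserved genes, planted-enriched
   gene sets and planted gene–metabolite correlations, so the whole
   pipeline is testable offline with known ground truth.

All tabular I/O is plain TSV (GMT for gene sets, BLAST outfmt 6 for hit
tables); outputs carry `#`-prefixed metadata headers and are byte-for-byte
reproducible for a fixed config and seed.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (analytic Z→p
correspondences, exhaustive GSEA oracle equivalence, Stouffer closed
forms, full-scale parameter recovery, null calibration, antisymmetry).

## CLI

```sh
# full synthetic run (simulate -> DE -> signatures -> map -> correlate ->
# integrate -> GSEA -> metabolites), everything seeded:
sigmeta run --config config.yaml

# individual stages:
sigmeta simulate --outdir data/ --seed 1
sigmeta de --counts data/counts_hsapiens_c1.tsv --metadata data/metadata.tsv \
    --contrast-id hsapiens_c1 --out de.tsv
sigmeta signature --de-table de.tsv --out sig.tsv
sigmeta orthomap --signature sig.tsv --table data/orthologs_hsapiens.tsv --out ref.tsv
sigmeta gsea --signature ref.tsv --gmt sets.gmt --nperm 10000 --out enrichment.tsv
```

A minimal `config.yaml`:

```yaml
outdir: results/run1
seed: 7
n_perm: 1000
min_species: 6
z_hi: 10
z_lo: 5
sd_cut: 10
```

With no input paths configured, `run` simulates a default 7-species /
110-contrast study; point `counts_dir`, `gmt`, `reference_expression` /
`reference_metabolites` at your own TSVs to analyze real data.

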