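# ssrkit

Analysis toolkit for **dominant-scored polyploid SSR fingerprints**, built for
genebank collection management: genetic diversity summaries, relationship
analysis, redundancy pruning, and clonal identity verification for
presence/absence (0/1, missing = 9) marker data such as hexaploid sweetpotato
SSR panels.

## What it does

- **`ssrkit.genotype_io`** — the core data model: marker panels with per-locus
  allele inventories, accession × (marker, allele) score matrices with
  block-level missingness, passport metadata, reading/writing a canonical
  CSV dialect, validation, subsetting and cross-collection merging.
- **`ssrkit.diversity_stats`** — per-marker allele counts and mean alleles per
  individual, equal-dosage allele frequencies (a sample presenting *k* alleles
  contributes 1/*k* to each), Botstein PIC, expected heterozygosity, and
  group-level Fst.
- **`ssrkit.distance_tree`** — pairwise Jaccard dissimilarity (joint absences
  ignored, missing blocks handled pairwise-complete), Saitou–Nei neighbor
  joining with deterministic tie-breaking and Newick output, and classical
  PCoA.
- **`ssrkit.redundancy`** — duplicate-group detection at a similarity
  threshold (single- or complete-linkage) and pruning to one representative
  per group, plus pairwise-distance histograms.
- **`ssrkit.identity`** — paired true-to-type verification (e.g. mother plant
  vs in-vitro culture) and reconciliation of a query collection against a
  reference collection using declared-transfer / name-match links.
- **`ssrkit.synthetic_data`** — a structured hexaploid fingerprint simulator
  (Dirichlet population spectra, admixture, multinomial allele-copy draws
  collapsed to presence/absence, clones, scoring errors, missingness, label
  swaps) with full ground truth, so every pipeline stage is testable without
  external data.

## CLI

All commands operate on the canonical CSV dialect
(`accession_id,<marker>_<allele>,...`, cells 0/1/9; sample rows may be
source-qualified as `id|mother` / `id|invitro`).

```bash
ssrkit stats   --input matrix.csv --output stats.csv \
               --passport passport.csv --group-by country
ssrkit dist    --input matrix.csv --output dist.csv
ssrkit tree    --input matrix.csv --output tree.nwk          # or --distances
ssrkit pcoa    --input matrix.csv --output coords.csv --axes 2
ssrkit prune   --input matrix.csv --output pruned.csv \
               --threshold 0.95 --linkage single
ssrkit verify  --input matrix.csv --pairs pairs.csv --output verdicts.csv
ssrkit reconcile --input query.csv --reference ref.csv --links links.csv \
               --output report.csv --match-threshold 1.0 \
               --uniqueness-threshold 0.95
ssrkit neighbors --input query.csv --reference ref.csv --k 100 \
               --output hits.csv
ssrkit simulate --config sim.yaml --out outdir/ --seed 1
```

## Conventions worth knowing

- A (sample, marker) block is either fully scored or missing; blocks mixing
  9s with scores are flagged by `genotype_io.validate` and treated as missing
  downstream.
- Jaccard distances are undefined (NaN) for pairs with no co-scored presence
  union; such pairs never merge duplicate groups and must be resolved before
  tree building.
- Duplicate-group representatives are the lexicographically smallest sample
  id, making pruning independent of input row order.
- Fst estimates below zero (sampling noise) are clamped to 0 and flagged.
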