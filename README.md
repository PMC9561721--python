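# sigportrait

Consensus gene-expression **portraits** and **signature-reversal** treatment
scoring for differential-expression (DE) meta-analysis.

Given per-study DE tables (GEO2R/GREIN style: gene symbol, p-value, signed
fold change), the package:

- converts each table to signed dysregulation scores
  (`sign1 = -log10(p) × sgn(direction)`), with symbol normalization and
  alias-map updating;
- aggregates many studies into a consensus **portrait** by summing
  directional rank-stratum weights (default: weight 8 for directional ranks
  1–1000 decreasing to 1 for 7001–8000), with a strict `> 2/3` presence
  filter and a two-datasets-per-independent-study cap (composites drop the
  cap);
- compares two signed signatures via the **A/B/C/D quadrant** hypergeometric
  analysis of their top-1000 up/down lists (universe = jointly measured
  genes) and derives the congruence score (`nlpA + nlpD − nlpB − nlpC`) and
  the treatment-reversal score (its negation), ranked treatment screens,
  reversed-gene sets and theoretical treatment combinations
  (inclusion-exclusion unions);
- computes **RRHO** (rank-rank hypergeometric overlap) grids with signed
  −log10 tails and renders diverging heatmaps;
- generates **synthetic multi-study collections** with a planted consensus
  signal and treatments with a controllable reversal fraction, so every
  stage is testable end-to-end without downloads.

## CLI

```sh
# synthetic collection: 6 studies + 1 planted reverser + 9 nulls
sigportrait simulate --out data/ --seed 1 --n-treatments 10 --reversal-fraction 0.8

# DE table -> signed scores
sigportrait ingest data/SIM00.tsv --out scores/SIM00.tsv

# consensus portrait (manifest enforces the per-study cap)
sigportrait portrait scores/SIM*.tsv --manifest manifest.tsv --out portrait.tsv

# treatment composite (no cap)
sigportrait composite scores/TRT*.tsv --out composite.tsv

# rank treatments against a disease signature
sigportrait score --disease portrait.tsv scores/TRT*.tsv --out ranked.tsv

# union of reversed genes across treatments
sigportrait combine --disease portrait.tsv scores/TRT000.tsv scores/TRT001.tsv --out combined.txt

# RRHO heatmap of two signatures
sigportrait rrho scores/SIM00.tsv scores/TRT000.tsv --out-prefix rrho_map

# full pipeline from a YAML config
sigportrait run run.yaml
```

`sigportrait run` consumes a YAML `RunConfig` (keys: `disease_tables`,
`manifest`, `treatment_tables`, `out_dir`, `n_top`, `stratum_bounds`,
`stratum_weights`, `min_presence_fraction`, `shared_gene_threshold`,
`strict_compatibility`, `p_floor`, `rrho_step`, `columns`) and writes
`portrait.tsv`, `treatments_ranked.tsv`, reversed-gene lists, RRHO
matrix/heatmap and a `run_manifest.json` auditing all parameters and
drop counts. Reruns are byte-identical.

## Package layout

| module | contents |
| --- | --- |
| `sigportrait.ingest` | DE-table parsing, sign1 transform, alias maps, exchange format |
| `sigportrait.portrait` | weight schemes, directional ranking, portrait/composite builds |
| `sigportrait.overlap` | hypergeometric overlaps, quadrants, scores, screens, combinations |
| `sigportrait.rrho` | RRHO grids and heatmap rendering |
| `sigportrait.simulate` | synthetic collections, treatments, alias injection |
| `sigportrait.pipeline` | end-to-end orchestration and run manifests |
| `sigportrait.cli` | `sigportrait` command-line entry point |
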