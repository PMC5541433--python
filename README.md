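# micromat

Analysis toolkit for longitudinal microbiome cohorts, built around three
analyses commonly applied to growth-trial data:

* **Microbiota-age modelling and maturation index** (`micromat.maturity`):
  regression forests trained on a reference group rank age-discriminatory
  taxa (mean importance over repeated fits), cross-validation selects the
  minimal top-k taxon subset, and a smoothing spline of predicted
  microbiota age vs chronologic age locates each group's maturity plateau.
  The maturation index (IMMI) of a group is the earliest day its curve
  reaches the reference group's full-maturity microbiota age.
* **Reporter-score pathway enrichment** (`micromat.reporter`): per-KO
  Kruskal–Wallis tests with BH adjustment, inverse-normal Z-scores
  `z = isf(p_adj)`, pathway aggregation `sum(z)/sqrt(k)`, and
  standardization against 1000 random same-size KO sets; pathways with an
  adjusted score ≥ 1.6 are called enriched.
* **Co-occurrence networks** (`micromat.conet`): Spearman adjacency with
  margin-permutation p-values, signed edge filtering, density, Freeman
  degree centralization, core (largest) component, sign-partitioned
  neighbor queries, and pooled-plus-per-period network dynamics.

Supporting modules: `micromat.tablesio` (TSV feature tables, metadata,
pathway maps, normalization, rarefaction without replacement),
`micromat.commstats` (alpha diversity, Bray–Curtis distances, vectorized
PERMANOVA/ANOSIM, per-genus Kruskal tests), `micromat.simgen` (synthetic
cohorts with warped logistic taxon trajectories, KO studies with planted
pathway shifts, correlated taxa blocks — all with ground truth), and
`micromat.pipeline` (YAML-config orchestration).

## CLI

```bash
# synthetic data with ground truth
micromat simulate cohort  --config cohort.yaml --seed 1 --out sim/
micromat simulate kostudy --config kostudy.yaml --seed 1 --out sim/
micromat simulate netblock --seed 1 --out sim/

# analyses
micromat maturity  --table t.tsv --metadata m.tsv --control-group control \
                   --ntree 5000 --iters 100 --folds 10 --delta 0.05 --seed 1 --out out/
micromat reporter  --ko-table k.tsv --metadata m.tsv --pathways map.tsv \
                   --threshold 1.6 --nsets 1000 --seed 1 --out out/
micromat network   --table t.tsv --metadata m.tsv --periods 7,28,42 \
                   --min-rho 0.3 --max-q 0.05 --seed 1 --out out/
micromat diversity --table t.tsv --metadata m.tsv --permutations 999 --seed 1 --out out/

# end-to-end from one config
micromat pipeline validate --config run.yaml
micromat pipeline run --config run.yaml
```

Feature tables are TSV, taxa × samples, first header cell `#ID`. Metadata
columns: `sample_id subject_id group age_days`. Pathway maps: one
`pathway_id ko_id` pair per row.

A minimal pipeline config:

```yaml
version: 1
master_seed: 7
output_dir: out/
simulate:
  cohort:
    n_taxa: 30
    n_age_taxa: 12
    sampling_days: [3, 6, 9, 12, 15, 18, 21, 24, 27, 30, 33, 36, 39, 42]
    n_per_day: 6
    groups: [[control, 1.0], [fast, 2.0], [slow, 0.75]]
maturity:
  table: simulated
  metadata: simulated
  control_group: control
  n_trees: 500
  n_importance_iters: 5
diversity:
  table: simulated
  metadata: simulated
```

## Notes on method choices

* Rarefaction is multivariate-hypergeometric subsampling (without
  replacement); shallow samples are an error unless explicitly dropped.
* Training-group microbiota ages use out-of-bag predictions to avoid
  optimistic maturity curves (in-sample mode available via flag).
* The maturity plateau is operationalized as the earliest daily-grid age
  whose fitted value reaches `(1 - delta)` of the curve maximum
  (`delta = 0.05` by default).
* Reporter scores are significance-only (direction of change is not
  encoded); background sets are drawn from all *tested* KOs.
* Network edge criteria (`|rho| >= 0.3`, BH `q <= 0.05`, ≥999
  permutations) are conventional defaults and fully CLI-exposed; no
  compositionality correction is applied to the Spearman step.
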