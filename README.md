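# modfinger

Module-fingerprint analysis of blood transcriptomes: a tested, reusable
pipeline for quantifying disease activity from normalized log2 expression
matrices.

Given a gene-by-sample matrix, group labels and a collection of named gene
modules (GMT), the pipeline provides:

- **dge** — two-group differential expression with empirical-Bayes variance
  moderation (posterior variance `(d0·s0² + d_g·s_g²)/(d0+d_g)`, moment
  estimation of the prior from log sample variances) and Benjamini–Hochberg
  FDR control.
- **fingerprint** — the module fingerprint statistic: per module, the
  percentage of member genes significantly up- or down-regulated in a
  contrast, plus multi-contrast grids and rendered heat-grids.
- **signature** — minimal discriminating gene lists by nearest shrunken
  centroids with stratified cross-validated threshold selection (smallest
  error, then fewest genes).
- **clustering** — hierarchical clustering of samples on significant genes
  (correlation/euclidean, average/complete/ward) with an activity-group
  separation score and clustered heatmaps.
- **enrichment** — hypergeometric over-representation of a query gene list
  against user-supplied gene sets with Bonferroni (and BH) control.
- **synthetic_data** — a seeded generator of module-structured cohorts
  (scaled inverse-chi-square gene variances, planted directional module
  shifts, penetrance, optional batch term) with a per-gene truth table, so
  the entire pipeline is verifiable offline.
- **io_formats** — strict readers/writers for TSV/GCT 1.2 expression, GMT
  gene sets, metadata TSV, result tables (bit-exact round trips) and
  uncompressed GEO series-matrix files.

## Command line

Each stage is a subcommand; `modfinger run` chains them from one YAML
config with a manifest (sha256 per artifact, seed, versions, stage times).

```bash
# seeded synthetic cohorts (group sizes 13/25/51/95, planted modules)
modfinger simulate --seed 17 --n-genes 1500 --out-prefix sim/

# moderated differential expression, BH 0.05
modfinger dge --expr sim/expr.tsv --meta sim/meta.tsv \
    --contrast high,none --alpha 0.05 --out dge.tsv

# module fingerprint
modfinger fingerprint --dge dge.tsv --modules sim/modules.gmt \
    --alpha 0.05 --out fp.tsv

# minimal signature (nearest shrunken centroids, 10-fold CV)
modfinger signature --expr expr.tsv --meta meta.tsv \
    --folds 10 --seed 17 --out model.json

# clustering + separation score + heatmap
modfinger cluster --expr sim/expr.tsv --dge dge.tsv --meta sim/meta.tsv \
    --target high --out heatmap.png --report sep.tsv

# gene-set over-representation
modfinger enrich --query genes.txt --sets sets.gmt \
    --universe universe.txt --out enrich.tsv
```

Full pipeline:

```bash
modfinger run --config run.yaml
```

```yaml
# run.yaml
seed: 17
out_dir: out
simulate: {paper_like: true, n_genes: 1500}
contrasts:
  - {id: high_vs_none, groups: [high, none]}
  - {id: typical_vs_healthy, groups: [typical, healthy]}
alpha: 0.05
signature: {folds: 5}
cluster: {target: high, distance: correlation, linkage: average}
```

Replace `simulate:` with `inputs: {expr: X.tsv, meta: meta.tsv,
modules: modules.gmt}` to run on real data. Two runs with the same config
and seed produce bit-identical outputs.

## Reproduction recipe (GSE11909)

The comparison harness never downloads. To reproduce the published
pediatric fingerprint column:

1. Obtain the GSE11909 series matrices (GPL96/U133A, and GPL97/U133B where
   deposited — note 6 of 12 healthy-control U133B arrays are missing from
   the deposit) and decompress them.
2. Build `samples.tsv` assigning each GSM to `sle` (untreated pediatric
   SLE) or `healthy` from the series sample annotations; the harness
   requires this explicit mapping rather than guessing.
3. Provide the module definitions as GMT (module id, label, member genes or
   probes) and, if the GMT uses gene symbols, a `gene_map.tsv`
   probe-to-symbol map; duplicate probes per gene are collapsed by maximal
   mean intensity (`--collapse`, also `mean`/`none`).
4. Write the published percentages as a reference TSV
   (`module_id  pct_up  pct_down`) and run:

```bash
modfinger repro-gse11909 --expr GSE11909_series_matrix.txt \
    --meta samples.tsv --modules modules.gmt --reference table3.tsv \
    --contrast sle,healthy --out comparison.tsv
```

The output is a side-by-side report (computed vs reference, differences,
`within_tol` flag) — a reproduction report, not a test gate. Percentages
are reported both ways via counts: `n_up/n_down` over `n_measured`
(default denominator) or `n_total`.

## Library use

```python
from modfinger import (simulate_cohorts, make_paper_like_design,
                       moderated_t, module_fingerprint, nsc_cv,
                       cluster_samples, separation_score,
                       hypergeometric_enrichment)

expr, meta, modules, truth = simulate_cohorts(make_paper_like_design(seed=1))
table = moderated_t(expr, meta, ("high", "none"))
fp = module_fingerprint(table, modules, alpha=0.05)
print(fp.table[["module_id", "pct_up", "pct_down"]])
```
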