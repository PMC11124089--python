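# metadrug

Drug nomination and biomarker discovery for tumors with high glycolysis /
OXPHOS activity, exercised end-to-end on synthetic data with planted ground
truth.

The pipeline:

1. **Synthetic universe** (`metadrug.synth`) — cell-line panel with measured
   drug-response AUCs driven by a latent glycolysis/OXPHOS program, two
   batch-shifted patient cohorts, drug metadata, a STRING-style PPI edge
   list with planted hubs, pre/post perturbation profiles, and survival
   times driven by a marker gene. Everything is deterministic for a fixed
   seed, and the planted structure is recorded in a `GroundTruth` object.
2. **Signature scoring** (`metadrug.scoring`) — single-sample gene-set
   variation scores (Gaussian-kernel CDF statistic, weighted KS random
   walk), min–max rescaling to 0–100 per cohort, an AR activity score on
   [0, 1], and AR(low)Gly(high) stratification.
3. **Response imputation** (`metadrug.imputation`) — two-batch empirical-
   Bayes (ComBat-style) expression harmonization, Box–Cox response
   transform, top-50% variance gene selection, and per-drug ridge models
   with seeded 10-fold CV over a log-spaced penalty grid (1-SE rule with an
   intercept-only sentinel, so drugs with no expression signal collapse to
   a constant model).
4. **Drug nomination** (`metadrug.nomination`) — per-drug OLS of signature
   score on predicted response (age-adjusted for OXPHOS when available),
   Benjamini–Hochberg FDR per (cohort × source × score) family, Drug_HG /
   Drug_OX / Drug_DE sets with cross-cohort intersection, primary-MOA
   summary, and the four-filter candidate cascade (development status,
   cross-dataset consistency, measured-response sign, perturbation
   activation).
5. **Network biomarkers** (`metadrug.network`) — |Spearman| ≥ 0.4
   preselection, induced PPI subnetwork at confidence ≥ 700, 12 topological
   centrality methods (Betweenness, Bottleneck, Closeness, Clustering
   Coefficient, Degree, DMNC, EcCentricity, EPC, MCC, MNC, Radiality,
   Stress), top-50 consensus hubs, signed Spearman biomarker filter, and a
   Welch test of stratified drug response.
6. **Survival** (`metadrug.survival`) — Kaplan–Meier curves and the
   two-group log-rank test on a median split of biomarker expression.

## CLI

```bash
# write a full synthetic universe (expression TSVs, AUC/metadata CSVs,
# GMT, STRING-style edges, clinical tables, ground-truth JSON)
metadrug simulate --out universe/

# individual stages
metadrug score --expression universe/expression_EC-like.tsv \
    --gmt universe/gene_sets.gmt --out scores.csv
metadrug impute --train-expression universe/ccl_expression.tsv \
    --target-expression universe/expression_EC-like.tsv \
    --auc universe/measured_auc.csv --out imputed.csv
metadrug survive --expression universe/expression_EC-like.tsv \
    --clinical universe/clinical_EC-like.csv --gene G0042 --out surv.json

# the whole analysis in one command
metadrug run-all --out run/ --seed 1
```

All numeric conventions (α = 0.05, feature fraction 0.5, preselection
threshold 0.4, confidence floor 700, top-k 50, consensus tier, 1000
percolation replicates) live in `PipelineConfig` and can be overridden from
a YAML config passed with `--config`.

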