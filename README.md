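# ancineq

Socio-economic inequality analysis of eight-or-more antenatal-care (ANC)
visits: DHS-style survey weighting and multi-country pooling, weighted
logistic regression, concentration curves and concentration indices (CIX) by
wealth and education, and an elasticity-based decomposition of the CIX into
per-covariate contributions. A synthetic multi-country survey generator with
known ground truth makes every stage testable without restricted microdata.

## Layout

| module | role |
| --- | --- |
| `ancineq.synthetic` | multi-country survey generator: latent-affluence asset model, PCA wealth index, ordered-logit education, logistic outcome with calibratable prevalence |
| `ancineq.survey` | ingestion: ANC recoding (8+ dichotomy), `v005`-style weight derivation, weight de-normalization, complete-case filtering, country pooling |
| `ancineq.descriptives` | weighted prevalence with logit-Wald CIs (Kish effective n) and cross-tabulations |
| `ancineq.selection` | best-subset AIC model selection and VIF screening |
| `ancineq.regression` | weighted ML logistic fit (aORs, Wald CIs) and average marginal effects |
| `ancineq.inequality` | weighted fractional mid-ranks, concentration curves, CIX (`2·cov_w(y,r)/μ`), robust convenient-regression inference, per-country results |
| `ancineq.decomposition` | per-category contributions `η_k·C_k`, closure residual, percentage aggregation |
| `ancineq.pipeline` / `ancineq.cli` | end-to-end orchestration with a hashed artifact manifest |

`ancineq.reference_tables` bundles the published decomposition tables'
printed contribution columns, used only as inputs to aggregation
regression tests (the underlying microdata are restricted).

## CLI

```sh
# synthetic fixture (CSV + ground-truth JSON)
ancineq simulate --seed 1 --out scratch/fix --n-per-country 2000

# pool per-country files with de-normalized weights
ancineq prepare --in scratch/fix/women.csv --country-meta meta.yaml \
    --out scratch/pooled.csv

# individual stages
ancineq describe  --pooled scratch/pooled.csv --out scratch/table2.csv
ancineq select    --pooled scratch/pooled.csv --candidates 2 --out scratch/sel.json
ancineq regress   --pooled scratch/pooled.csv --out scratch/aor.csv
ancineq cix       --pooled scratch/pooled.csv --stratifier wealth --by-country \
    --out scratch/cix
ancineq decompose --pooled scratch/pooled.csv --stratifier wealth \
    --out scratch/decomp.csv

# everything from one config (or a default synthetic run)
ancineq run-all --seed 1 --out scratch/run
ancineq run-all --config config.yaml
```

`meta.yaml` maps each country to its female-population total (and optional
eligible sample size), which drives the weight de-normalization:

```yaml
AA: {total_population: 2400000, sample_n: 6000}
BB: {total_population: 1500000}
```

## Conventions that matter

- Wealth quintiles are ordered poorest→richest (codes 1–5) and education
  no-education→higher (codes 1–6); CIX signs follow this order (positive =
  concentrated among the richer / more educated).
- Tied stratifier values share a weighted mid-rank block, so ranks are
  deterministic and order-invariant.
- The headline CIX is the uncorrected index; Wagstaff/Erreygers rescalings
  for the binary outcome are available as labelled diagnostics
  (`ancineq.inequality.corrected_index`).
- The decomposition residual is defined by closure
  (`C_total − Σ contributions`), so the additive identity is exact; a
  generalized-concentration-index-of-errors diagnostic is provided and
  coincides under a linear model.
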