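# bcproteodyn

Analysis pipeline for DIA proteomics of breast-cancer cell-line panels:
matrix-level quality control, protein-complex co-expression, TNBC
differential expression, multi-omics elastic-net drug-response prediction
with nested cross-validation, and drug-perturbation time-course dynamics.

## Who this is for

Proteomics and pharmacogenomics analysts working with quantitative
protein × sample matrices (log2 intensities, 30–50 % intensity-dependent
missingness), matched transcript/mutation layers, drug-response tables
(log10 IC50), and drug-perturbation time courses.  Every analysis stage is
also exercised end-to-end on synthetic cohorts with planted ground truth,
so the statistical behaviour of each estimator is testable without any
deposited dataset.

## The methods at the core

**Nested cross-validated elastic net.**  For each drug, response *y*
(log10 IC50 over cell lines) is modelled from omics features *X* by
minimising

    (1/2n)·Σᵢ (yᵢ − β₀ − xᵢβ)² + λ·( α·‖β‖₁ + (1−α)/2·‖β‖₂² )

(α, λ) are tuned by replicated k-fold CV; coefficients are averaged over
200 refits on random 90 % subsamples of the lines; predictors are ranked by
|mean coefficient|; the model size k is the smallest within one standard
error of the minimum 10-fold CV error of top-k OLS (1-SE rule); and the
whole procedure is re-run inside a leave-one-out loop so predictive power —
Pearson r(observed, predicted) — is leakage-free.

**Perturbation dynamics.**  Replicate-averaged profiles over
{0, 4, 12, 24, 48, 72} h are screened for proteins whose expression tracks
log10 IC50 across lines (|mean per-time-point r| > 0.7), clustered by fuzzy
c-means, and filtered for opposite dynamics: B-H-adjusted ANOVA p < 0.05
across time, |last-vs-first fold change| > 2, monotone-consistent direction,
with the direction consistent in a majority of TNBC lines and reversed in a
majority of non-TNBC lines.  Persistently dysregulated proteins (PDPs) are
0 h-vs-72 h differential proteins (B-H adjusted p < 0.05, FC > 1.5 or
< 0.67) shared by more than 60 % of TNBC lines.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Simulate a perturbation course (9 lines, 5 TNBC, 3 drugs, 6 time points,
3 replicates, 420 proteins with planted trends) and analyse it:

```sh
bcproteodyn simulate timecourse --spec tc_spec.yaml --seed 5 --out tcdata
bcproteodyn dynamics --timecourse tcdata --response tcdata/drug_response.tsv \
    --seed 5 --out dynout
```

with `tc_spec.yaml` containing `n_proteins: 420`.  This prints

```
30 opposite-dynamics proteins; PDPs: DRUG01=45, DRUG02=47, DRUG03=41
```

meaning: 30 proteins moved in opposite directions in TNBC vs non-TNBC lines
after treatment (the generator planted exactly 30; `tcdata/truth.tsv` lists
them), and 45/47/41 proteins per drug were persistently dysregulated
(0 h vs 72 h) in more than 60 % of the TNBC lines.  `dynout/` holds the
IC50-screen table, fuzzy-cluster memberships, the selected protein lists and
a `manifest.json` tying every output to the config hash and seed; re-running
with the same seed reproduces the files byte-for-byte.

The same pattern runs the cohort workflow (`bcproteodyn cohort --simulate
--preset fast --seed 7 --out out/`): QC → complex co-expression → TNBC
differential expression → elastic-net prediction, writing `qc_report.tsv`,
`complex_pairs.tsv`, `dep_table.tsv`, `signature.txt` and
`predictive_power.tsv`.

As a library, the estimators follow scikit-learn conventions:

```python
from bcproteodyn import NestedElasticNet, ENConfig
model = NestedElasticNet(config=ENConfig.preset("fast"), random_state=0)
model.fit(X_train, y_train)            # tune -> bootstrap -> rank -> top-k
model.predict(X_test)                  # OLS refit on model.selected_
```

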