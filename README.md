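# drugresponse

Predict a patient's chemotherapeutic response from **baseline tumor gene
expression alone**, using models trained on large cell-line drug screens.

Clinical cohorts with both pre-treatment expression profiles and a clean
response phenotype are small and rare; cell-line panels with baseline
expression and IC50s for over a hundred drugs are large and cheap. This
package trains a whole-genome penalized regression on such a panel and
transfers it to patients, handling the cross-platform batch problem in
between:

1. **Homogenize** — map both cohorts to a shared gene universe, remove
   per-gene cohort location/scale effects with parametric empirical-Bayes
   shrinkage (the ComBat model), and drop the 20% least variable genes.
2. **Fit** — power-transform the log IC50 phenotype (Yeo–Johnson or offset
   Box–Cox, exponent by profile maximum likelihood), then fit linear ridge
   regression of transformed IC50 on the standardized expression of every
   gene, with the penalty λ chosen automatically by exact leave-one-out GCV:
   β̂ = argmin ‖z − Xβ‖² + λ‖β‖².
   For targeted agents — where most screened lines never respond in-window
   and their IC50s are extrapolated noise — fit instead a **logistic ridge**
   on the 15 most sensitive vs the 55 most resistant lines, after selecting
   the 1,000 most differentially expressed genes by t-test.
3. **Predict** — apply the model to each patient's homogenized baseline
   profile: a predicted (transformed) log IC50, lower = more sensitive, or a
   predicted probability of sensitivity for the logistic pathway.
4. **Evaluate** — leave-one-out cross-validation on the panel (Pearson r of
   predicted vs measured IC50), ROC/AUC by the Mann–Whitney construction
   with empirical p-values from label permutations (default B = 100,000),
   t-tests / correlation / rank-sum tests, ordered-category medians, and a
   sensitive/resistant cut-point accuracy sweep.

Core computations are scikit-learn-style estimators (`LinearRidge`,
`LogisticRidge`, `EmpiricalBayesBatchCorrector`, `PhenotypePowerTransform`,
`VarianceFilter`) with `fit`/`predict`/`transform` and fitted attributes;
the module-level functions and the CLI are thin wrappers over them. A
seeded synthetic-data module generates cell-line panels, batch-shifted
clinical cohorts, and targeted-agent screens with known ground truth, so
every stage is testable without any download.

## Worked example

Simulate a 200-line, 1,000-gene training panel with a sparse expression →
log-IC50 signal (target R² = 0.7), a 40-patient cohort sharing that signal
but carrying per-gene platform shifts, and run the full pipeline:

```python
import numpy as np
import drugresponse as dr

expr, pheno, truth = dr.generate_cell_line_panel(seed=1)
cexpr, ctable, ctruth = dr.generate_clinical_cohort(truth, seed=1)

cv = dr.loocv_linear(expr, pheno)
print(f"LOOCV r = {cv.pearson.estimate:.3f} (P = {cv.pearson.p_value:.2e})")

res = dr.train_and_predict(expr, pheno, cexpr, mode="linear")
labels = np.asarray(ctable.response)           # 1 = responder
scores = res.predictions.predicted             # lower = more sensitive
roc = dr.roc_auc(scores, labels, positive_orientation="lower")
perm = dr.permutation_pvalue_auc(scores, labels, B=100_000, seed=1,
                                 positive_orientation="lower")
print(f"AUC = {roc.auc:.3f} (permutation P = {perm.p_value:.2e})")
sweep = dr.cutpoint_accuracy_sweep(scores, labels)
print(f"optimal cut-point accuracy = {sweep.optimal_accuracy:.2f}")
```

Output:

```
LOOCV r = 0.617 (P = 2.18e-22)
AUC = 0.795 (permutation P = 7.40e-04)
optimal cut-point accuracy = 0.72
```

The LOOCV r says the ridge model recovers most of the learnable in vitro
signal (the panel's true expression-driven R² is 0.7). The AUC of 0.80
means a randomly chosen responder gets a lower (more sensitive) predicted
IC50 than a random non-responder 80% of the time, and the permutation p
says an AUC that large arose in fewer than 1 in 1,000 random relabelings;
the cut-point sweep dichotomizes the continuous prediction and reports the
best achievable accuracy (72% here).

The same flow is available from the shell:

```bash
drugresponse simulate panel --seed 1 --out-prefix sim_
drugresponse loocv --expr sim_expr.tsv --pheno sim_ic50.tsv
drugresponse run --train-expr sim_expr.tsv --pheno sim_ic50.tsv \
    --test-expr cohort.tsv --response response.tsv --seed 1 --out-dir out/
```

`run` writes `predictions.tsv`, `report.json` (AUC, permutation p, t-test,
cut-point sweep) and `provenance.json` (config hash, input checksums).

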