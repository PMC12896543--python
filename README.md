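# triaxis

Tri-marker modelling of immune-checkpoint-blockade (ICB) response in lung
adenocarcinoma, re-built as a tested, synthetic-data-driven pipeline.

Only a minority of advanced lung adenocarcinoma patients benefit from
anti-PD-1/PD-L1 therapy, and the clinical standard biomarker — PD-L1
(CD274) expression — is only weakly predictive. This package implements a
composite, three-axis transcriptomic predictor and everything needed to
evaluate it honestly:

* **Characterization** — responder vs non-responder differential expression
  (Mann–Whitney U + Benjamini–Hochberg FDR), Kaplan–Meier/log-rank and Cox
  survival analysis, marker-gene correlation, and inverse-variance
  fixed-effect meta-analysis with Cochran's Q and I².
* **Discovery** (`TriAxisModel`) — an L1-penalized logistic regression over
  *BCL2A1* expression, *CD274* expression, and a 27-gene immune-activation
  ("hot") score, fitted with nested cross-validation (10 outer / 5 inner
  stratified folds). `fit()` returns a results object with out-of-fold
  metrics and a **locked model**: coefficients, intercept, penalty and a
  Youden-index classification threshold, frozen for external use.
* **Validation** — leave-one-cohort-out application of the locked model
  with equally weighted cohorts (macro-AUC), bootstrap CIs, heterogeneity
  I², intercept-only recalibration, decision-curve analysis over the
  15–50% risk-threshold band, and NRI/IDI against the CD274 baseline.
* **Deconvolution** — one-vs-rest CD8⁺ subtype marker selection
  (log₂FC > 1, AUROC > 0.7, adjusted p < 0.01), five reference-matrix
  variants (FULL / POS / NEG / noB / dropNB), a constrained least-squares
  solver (fractions ≥ 0, Σ ≤ 1), and a robustness battery: enrichment
  tests, patient-level permutation validation, bootstrap stability, and
  Gaussian noise perturbation.
* **Platform simulation** — noise models of targeted clinical assays
  (counting platforms and RT-qPCR archetypes: slope distortion, batch
  offsets, multiplicative noise, Poisson counting, abundance-weighted
  dropout) with concordance metrics (Spearman ρ, Cohen's κ, Lin's CCC,
  Bland–Altman) and parameter stress sweeps.

Every stage runs on data from the built-in synthetic generators, which
plant known effects (group shifts, a correlated hot program, a known
hazard ratio, subtype marker programs, responder-enriched subtypes) so
that recovery can be asserted against ground truth.

## The model

For sample *i* with features
x_i = (BCL2A1_i, CD274_i, HOT_i) (log₂ expression; HOT is the mean of
per-gene z-scores of the 27-gene program):

    logit P(response_i = 1) = β₀ + βᵀ x_i,   with L1 penalty on β

The penalty is selected by inner-loop AUC; out-of-fold probabilities from
the outer loop give honest discrimination estimates (ROC-AUC, PR-AUC,
Brier, calibration slope/intercept) and the Youden threshold
t* = argmax (sensitivity + specificity − 1). External cohorts are scored
by the locked (β₀, β, t*) with no refitting; performance is the
unweighted mean of per-cohort AUCs (macro-AUC).

## Worked example

```python
import triaxis as tx

cohort = tx.generate_bulk_cohort(tx.SimulationConfig(seed=1))
results = tx.TriAxisModel.from_cohort(cohort).fit(seed=1)
print(results.summary())

cohorts = tx.generate_multi_cohort(tx.SimulationConfig(seed=1))
report = tx.loco_validate(results.locked, cohorts, seed=1)
print(report.summary())
```

Output:

```
Tri-axis discovery model (L1 logistic, nested CV 10x5)
================================================================
feature             coef (raw scale)
----------------------------------------------------------------
BCL2A1                        0.9628
CD274                         1.0869
HOT                           2.2163
intercept                   -17.6150
----------------------------------------------------------------
penalty C = 4.64159   locked threshold = 0.421
OOF ROC-AUC = 0.895 (95% CI 0.806-0.983)   PR-AUC = 0.874
Brier = 0.124   calibration slope = 1.137, intercept = -0.228
Leave-one-cohort-out validation (locked model, no refitting)
================================================================
val1       n= 56  AUC=0.945 (0.880-0.990)  Brier=0.098
val2       n= 14  AUC=0.812 (0.510-1.000)  Brier=0.349
val3       n= 22  AUC=0.718 (0.473-0.932)  Brier=0.313
val4       n=  7  AUC=0.750 (0.250-1.000)  Brier=0.430
val5       n= 27  AUC=0.886 (0.733-0.991)  Brier=0.376
----------------------------------------------------------------
macro-AUC = 0.822 (95% CI 0.683-0.922); I2 = 11%
```

All three locked coefficients are positive — the planted directions —
and the locked model generalizes across the batch-shifted validation
cohorts (macro-AUC 0.822 with a chance-excluding CI). Per-cohort CIs are
wide for the small cohorts (n=7, n=14), which is exactly why cohorts are
equally weighted rather than pooled.

A thin CLI mirrors the stages:

```bash
triaxis synth --kind bulk --seed 1 --out data/
triaxis discover --seed 1 --out model.json
triaxis validate --model model.json --seed 1 --out report.json
triaxis deconv --variant FULL --seed 1 --out fractions.csv
triaxis platsim --parameter batch_variance_fraction --out sweep.csv
```

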