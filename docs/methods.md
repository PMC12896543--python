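# Methods

This note documents the statistical models, the synthetic data they are
exercised on, the defaults and why they were chosen, and the limits of
what the test suite demonstrates.

## Synthetic cohorts

The generators exist so that every pipeline stage can be validated
against *known* ground truth without external downloads. They are not
read-count simulators: expression is modelled directly on the log₂ scale
as Gaussian per gene, with gene-level means drawn from Uniform(2, 10)
and unit residual SD. This keeps every planted quantity available in
closed form (group mean differences, pairwise correlations, hazard
ratios), which is what the oracle tests need.

**Bulk cohorts** (`SimulationConfig`, defaults chosen once as the study
conditions):

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 60 | discovery cohort size |
| `responder_fraction` | 0.4 | responder prevalence |
| `marker_effect` | 1.0 | log₂FC of the focal marker in responders |
| `cd274_effect` | 1.0 | log₂FC of CD274 in responders (independent axis) |
| `hot_effect` | = `marker_effect` | log₂FC of each hot-program gene |
| `hot_gene_count` | 27 | size of the co-activated hot program |
| `hot_correlation` | 0.6 | pairwise correlation within the program |
| `survival_hr` | 0.43 | hazard ratio per +1 SD of focal expression |
| `censor_rate` | 0.3 | administratively censored fraction |

With unit residual SD a log₂FC of 1 corresponds to a single-marker AUC
of Φ(1/√2) ≈ 0.76, and the three planted axes together put the
tri-axis model's discrimination in the high 0.8s — a genuine
"tri-axis signal" in which each axis contributes, the regime the
model-ordering property (full ≥ reduced > single markers) presumes.

The hot program uses a one-factor Gaussian model
(x = μ + √ρ·f + √(1−ρ)·ε), the simplest construction with tunable
pairwise correlation ρ. Survival is exponential with log-hazard
log(HR)·z(focal); censoring is administrative at the empirical survival
quantile that censors exactly `censor_rate` of the cohort. External
validation cohorts default to sizes (56, 14, 22, 7, 27) and receive
independent per-gene batch offsets ~ Normal(0, batch_sd²), batch_sd 0.5
by default, on the log₂ scale.

**Cell populations** (`CellConfig`): 7 CD8⁺ subtypes at desk scale
(3,000 cells, 10 patients by default — two orders of magnitude below a
real atlas, with the same statistical structure). Each subtype
over-expresses 12 private marker genes by 2 log₂ units; responders
(MPR) carry 2× frequency weights for the Trm and proliferating subsets;
the focal marker is detected in 60% of cells of its designated subtypes
vs 10% elsewhere. A shared per-cell activation factor (loading 1.3 on
the log₂ scale) ties the focal gene to its subtypes' markers, which
puts their pairwise correlation among focal-positive cells in the
0.5–0.6 range; this planted redundancy is what the dropNB
reference-ablation analysis is designed to expose.

What the generators deliberately do **not** emulate: negative-binomial
count noise, library-size variation, gene-length effects, ambient RNA,
doublets, or real batch structure. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration under the stated
generative model, not performance on real sequencing data.

## Characterization statistics

Differential expression is an unadjusted Mann–Whitney U test per gene
(tie-corrected normal approximation; exact for small untied samples via
`method`), with BH step-up over all tested genes; constant genes get
p = 1 by convention. A covariate-adjusted mode (OLS of log expression
on group + covariates) is available but secondary — the rank test is
the primary analysis. log₂FC is the difference of responder and
non-responder means on the log₂ scale.

Survival uses lifelines: Kaplan–Meier per group, the standard-variance
log-rank test, and Cox partial likelihood with Breslow tie handling
(Efron behind a flag). The Cox result reports the first covariate's HR
with a Wald 95% CI; non-convergence and separation are surfaced as
diagnostics rather than exceptions.

Fixed-effect meta-analysis is inverse-variance pooling with Cochran's
Q and I² = max(0, (Q−df)/Q)·100. Random-effects pooling is not
implemented: the use case is a homogeneous set of cohorts, where the
two coincide. Note that for *sampled* homogeneous studies Q ~ χ²(df),
so I² = 0 is a ~54% event per draw (df = 20); only identical inputs
give I² = 0 deterministically. The tests assert exactly this
distinction.

## Discovery model

Preprocessing: optional log₂(x+1) for counts, an abundance floor
(default: mean log₂ < 1 removed; the floor is configuration), then
per-gene robust z-scores (x − median)/(1.4826·MAD), dropping MAD-0
genes with a warning.

Features are built per cohort: raw log₂ BCL2A1 and CD274 plus the hot
score (mean of per-gene z-scores across the cohort's samples, signed by
direction; zero-variance genes contribute 0). Because each feature is
computed within its cohort, additive cohort-level batch offsets cancel,
which is what lets a locked model transfer across shifted cohorts.

Nested CV: stratified 10 outer / 5 inner folds; the inner loop selects
the L1 penalty C from a log grid (10⁻²…10², 7 points) by mean
inner-fold AUC, ties resolved toward the stronger penalty. Feature
standardization is re-fit inside each training split — held-out samples
never influence their fold's scaler or penalty. Out-of-fold
probabilities cover each sample exactly once and feed all reported
metrics: rank-based ROC-AUC (DeLong CI), average-precision PR-AUC (step
integral, avoiding interpolation ambiguity), Brier score, and
calibration slope/intercept from a logistic regression of the outcome
on logit(p) (the classical recalibration-regression convention).

Locking: the final penalty is re-selected by 5-fold CV on the full
discovery set (mirroring the inner loop), the model is re-fit on all
samples, and the scaler is folded into raw-scale coefficients so the
locked artifact is a plain affine-plus-sigmoid map. The threshold is
the Youden maximizer over the out-of-fold probabilities, ties broken
toward higher specificity, returned as the midpoint of the optimal
threshold interval. A penalty that zeroes every coefficient is refused.
The locked model serializes to versioned JSON and round-trips exactly.

The DeLong test for paired AUC comparison uses midrank placement values
and their empirical covariance; identical predictions return p = 1 by
construction.

## External validation

`loco_validate` applies the locked coefficients and threshold unchanged
to each cohort. Per-cohort AUC CIs are percentile bootstrap (2000
resamples, seeded) — the CI method was an open choice and bootstrap
makes the fewest assumptions at n as small as 7. The macro-AUC is the
unweighted mean over cohorts (each cohort is one validation unit); its
CI averages within-cohort bootstrap draws. Heterogeneity of cohort AUCs
is Cochran's Q on logit-AUCs with bootstrap SEs, reported as I².
Single-class cohorts (possible at n = 7) are excluded from AUC
averaging but keep their threshold metrics, since AUC is undefined
for them.

Clinical-utility layers: net benefit NB(t) = TP/n − FP/n·t/(1−t) with
treatment rule p ≥ t over the 0.15–0.50 grid; two-category NRI at a
stated threshold plus IDI as the discrimination-slope difference;
intercept-only recalibration by a Binomial GLM with offset logit(p)
(separation falls back to a bounded moment-matching step). Benchmarks
(TIDE/TIS/IPS/IFNG) are scored as configured gene-set signatures — gene
lists are registry configuration, and the shipped lists are synthetic
stand-ins defined over the generator's gene universe, not the published
definitions; full re-implementations of the multi-component published
algorithms are out of scope.

## Deconvolution

Marker selection is one-vs-rest per subtype: log₂FC of mean linear
expression (pseudocount 1), rank AUROC, Mann–Whitney p BH-adjusted
within subtype; the retention filters default to log₂FC > 1,
AUROC > 0.7, adjusted p < 0.01, and the cross-subtype union is
deduplicated.

Reference matrices are mean linear expression per subtype over the
marker union. POS/NEG restrict to focal-positive/negative cells; noB
deletes the focal gene's row; dropNB additionally deletes markers with
|Pearson r| > 0.5 to the focal gene — computed on log₂(1+x) among
focal-positive cells, because zeros from the focal-negative compartment
carry no co-regulation information. The 0.5 cutoff is configurable.

The solver minimizes ‖R·f − b‖² subject to f ≥ 0 and Σf ≤ 1, the
remainder being "other" mass. Implementation: one batched unconstrained
least-squares over all samples, with an SLSQP refit only where a
constraint is active — exact (≤ 1e-6, in practice machine precision)
for noise-free mixtures and fast enough for 10⁴ samples in seconds.
Cell-type-specific mRNA-content renormalization and tumor-profile
handling are deliberately not modelled; the robustness framework, not
the solver brand, is the point. Log-scale bulk input must be
exponentiated by the caller (deconvolution is linear in transcript
abundance).

Robustness battery: Mann–Whitney enrichment per subtype with BH across
subtypes (Δ reported on the fraction scale, with an optional scale
factor since fractions are ≤ 1); permutation validation shuffles labels
at the *patient* level (cells within a patient are not exchangeable),
with add-one empirical p-values; bootstrap stability resamples patients
with replacement (per-sample fits are independent, so this reduces to
resampling fraction rows); noise perturbation multiplies bulk entries
by 1 + ε, ε ~ N(0, rel_sd²) truncated at −1, and reports the mean
absolute fraction shift and correlation to baseline.

## Platform simulation

The per-gene pipeline, in order: slope distortion around the gene mean
(e_g ~ U(1−δ, 1+δ)); batch offsets with per-gene variance equal to
`batch_variance_fraction` × signal variance, of which
`batch_gene_correlation` (default 0.5) is a run-level component shared
across genes — shared offsets survive multi-gene averaging, which is
why batch variance degrades score-level concordance far more than
matched-magnitude independent noise (the ordering the stress tests
assert); additive log₂ noise with SD √(ln(1+cv²))/ln 2 (the exact
lognormal-CV mapping); an optional Poisson counting layer on the linear
scale; and dropout to the matrix floor with per-gene probability linear
in inverted abundance rank, averaging `dropout_rate`. An all-zero
profile reproduces the input bit-identically.

Preset profiles are honest archetypes (counting platforms: Poisson +
low CV, no batch term; RT-qPCR: efficiency distortion + batch term),
not vendor calibrations; every value is configuration. Concordance
reports Spearman ρ with a seeded percentile-bootstrap CI, Cohen's κ on
high/low calls at the reference median (or a supplied cutoff), Lin's
CCC from population moments, and Bland–Altman bias ± 1.96 SD.
Signature ablation retains ⌈(1−fraction)·size⌉ genes uniformly at
random; negative-control signatures are random gene sets disjoint from
the tri-axis genes.

## Numerical conventions and degenerate inputs

Zero-variance genes contribute 0 to z-based scores and are reported as
missing (with the reason) in correlation outputs; constant genes get
p = 1 in rank tests; probabilities are clipped to [1e-7, 1−1e-7] before
logits; ties at a dichotomization cutoff are assigned the "cold"/low
class; Youden ties break toward specificity. All stochastic operations
take explicit seeds and are reproducible byte-for-byte.

## Problem sizes used in tests

The test and acceptance runs use desk-scale sizes chosen to make the
asserted properties statistically decidable: 20 repetitions for
seed-averaged recovery and ordering properties (validation cohorts of
5×80 samples for the ordering check, where the macro-AUC standard error
is small against the planted gaps), 200 repetitions for coverage-style
assertions (Cox CI coverage, permutation null coverage), 10⁴ random
mixtures for the solver's simplex invariant, and 1,500–3,000-cell
populations for marker recovery.

## Known limitations

* The generative model is Gaussian-on-log₂; none of the count-level
  artifacts of real RNA-seq are represented, and results on synthetic
  data bound what can be claimed about real cohorts.
* The hot-score gene list and the benchmark signature lists shipped in
  `triaxis/data` are synthetic stand-ins keyed to the generator's gene
  universe; real analyses must supply real gene lists via the registry.
* Fixed-effect meta-analysis only; inappropriate under real
  heterogeneity.
* The deconvolution solver omits mRNA-content renormalization, so
  estimated fractions are proportions of *signature-gene expression
  mass*, not of cell counts.
* Single-cell clustering/annotation is out of scope: the cell generator
  supplies labelled cells directly.
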