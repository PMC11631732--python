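# Methods

## Scope and data model

The package operates on four data modalities: (i) a genes × cells raw UMI
count matrix with per-cell metadata (patient, dataset/batch, cell type,
malignant flag), held as an `AnnData` with cells as observations and raw
counts preserved in `layers["counts"]` after normalization; (ii) IHC staining
tables (% cells at intensity 1+/2+/3+ per sample and marker); (iii) paired
IHC + RNA records for threshold calibration; (iv) bulk cohort expression
(samples × genes, log2(TPM+1)) with clinical columns (stage, survival time,
event flag). Malignant/normal labels are an *input*: the package does not
infer malignancy from copy-number profiles; a marker-score annotator is
provided only as a stand-in for external annotation tools.

## Single-cell preprocessing

**QC.** A cell is removed when it has fewer than 3 detected genes, fewer
than 200 total UMIs, or a mitochondrial fraction strictly above 20 %
(mitochondrial genes matched by a case-insensitive `MT-` symbol prefix,
regex configurable). The 3-detected-genes default is deliberately literal
and configurable; it is an unusually permissive threshold, and users working
with real data will typically raise it. Filtering is idempotent, and an
empty result is a reported warning, not an exception.

**Normalization.** Counts are scaled so each cell totals 10⁶ and then
log-transformed with natural `log1p`. The log base is recorded in `uns`;
zero entries map to zero, so the sparsity pattern is preserved exactly.

**HVG selection.** Genes are ranked by normalized dispersion: variance/mean
of the *pre-log* normalized values, z-scored within 20 equal-frequency bins
of the gene mean. Exactly-constant genes receive −∞ and can never displace a
variable gene; ties break alphabetically so selection is deterministic.
Variances are computed by the E[x²]−E[x]² identity on sparse columns with a
relative tolerance of 1e−12 to absorb cancellation noise.

**PCA and batch regression.** PCA (full SVD, genes centered) retains 30
components by default, truncating with a warning when the input rank is
lower. Batch correction fits, per feature, a ridge regression on one-hot
dataset indicators (closed form `β_b = n_b·ȳ_b/(n_b+λ)`, default λ = 1) and
subtracts the fitted effects recentred to mean zero, so the global feature
mean is preserved and λ → 0 equalizes per-batch means exactly. A single
batch is an identity transform with a warning.

## Target screening

The malignant-vs-normal classifier is a random forest (default 1000 trees)
on expression features. Cells are split 6:2:2 (stratified) into
train/test/validation; candidate settings (`max_features` grid) are compared
by mean ROC-AUC under 10-fold cross-validation on the training split, the
winner refit, and its test and validation AUCs reported. Gene importance is
**mean decrease in accuracy**: the drop in test-split accuracy when a
feature's column is permuted. Permuted copies are batch-stacked (64 features
per predict call), which makes the importance sweep roughly an order of
magnitude faster than per-feature prediction without changing the statistic.
Negative importances are kept and ranked as-is. The surfaceome intersection
is rank-then-filter: the ranking is restricted to the surface list and the
top-100 taken; a short intersection warns rather than errors. Whether the
classifier sees all genes or only surfaceome genes is the caller's choice
(both are supported); the demo pipeline feeds HVGs plus the planted surface
candidates.

The expressing cell fraction (ECF) is defined on **raw counts** (count > 0),
so it is invariant to normalization by construction.

## Co-expression analysis

Co-expression of anchor and partner in a cell means both raw counts > 0.
Fractions are computed per (patient, cell group); groups with fewer than 10
cells (configurable) are flagged invalid and excluded from tests, since
fraction estimates from a handful of cells are unstable. The
malignant-vs-stromal comparison is a two-sided Mann–Whitney rank-sum test
with one observation per patient on the malignant side and one per
(patient, stromal group) on the stromal side — exact null distribution when
both sides have ≤ 12 untied observations, normal approximation with tie
correction otherwise. The patient-level summary counts patients whose
fraction strictly exceeds the 10 % threshold. Partner ranking reports a
coverage view (median malignant fraction, descending) and a specificity view
(maximum stromal fraction, ascending).

## IHC scoring

H-score = 1·(%1+) + 2·(%2+) + 3·(%3+), bounded in [0, 300]; percentages must
sum to ≤ 100. Tiers are nested and inclusive: positive (H > 0), medium
(H ≥ 100), high (H ≥ 200). "Positive" is H > 0 to match the labels used for
RNA threshold calibration; sample-level dual positivity instead uses the
≥ 1 %-of-cells-stained-for-both rule, which is the published convention for
co-expression calls on consecutive sections. Cohort percentages are rounded
half-up to one decimal (via `decimal.Decimal`), the rule that reproduces
every arithmetically checkable published rate (63/64 → 98.4, 76/83 → 91.6,
79/83 → 95.2, 81/83 → 97.6, 504/517 → 97.5).

## Threshold calibration and coverage

TPM = (count/length) / Σ(count/length) × 10⁶ per sample; thresholds live on
the log2(TPM+1) scale. The ROC sweeps thresholds over ±∞ and the midpoints
between adjacent unique scores, calling a sample positive when
score ≥ threshold; AUC is the trapezoid integral and provably equals the
Mann–Whitney pair-counting concordance with ties counted ½ (property-tested
against an independent oracle). Youden's J = TPR − FPR selects the cut-off;
ties break toward the smallest threshold (maximal sensitivity), and an
all-equal score vector yields J = 0 with an undefined cut-off. Cohort
positivity uses a closed boundary (score ≥ θ), which makes coverage
monotone non-increasing in θ and the θ ≤ min(score) case exactly 100 %.

The published PDX-derived cut-offs (2.23 for EGFR, 1.5 for MUC1; AUCs
0.97/0.6) depend on that private PDX panel and cannot be recomputed here;
they are shipped as the documented constant `REFERENCE_CUTOFFS`, and the
package instead demonstrates *recovery of planted thresholds* on synthetic
paired panels.

## Survival analysis

Stage labels are collapsed to I–IV (sub-stage letters stripped) and the
cohort restricted to III/IV by default. "High" expression is per-gene median
split within the filtered cohort (strictly above the median) or, optionally,
the calibrated thresholds (closed boundary). The endpoint is any
(time, event) pair; no endpoint-specific logic. The Kaplan–Meier estimator
and the two-group log-rank test (hypergeometric O−E with variance
Σ d·(n₁/n)(n₂/n)(n−d)/(n−1), χ² with 1 df) are implemented directly because
their exact conventions are contracts of this package; they are cross-checked
against lifelines in the test suite. The univariate Cox model delegates to
lifelines' `CoxPHFitter` (Breslow ties); a separate score-test helper
evaluates the partial-likelihood score χ² at β = 0, which for a binary
covariate without tied event times equals the log-rank statistic — a
classical equivalence the tests verify to 1e−6.

## Synthetic data: what it emulates, and what it does not

**Single-cell cohort.** Gene g in a cell of type t is expressed with
probability π(g,t); expressed entries draw from a *zero-truncated* negative
binomial (Var = m + 0.5·m², dispersion configurable) whose mean is scaled by
a log-normal per-(batch, gene) multiplier (scale 0.15 by default). The
truncation makes π exactly the expected expressing-cell fraction, so planted
probabilities propagate unchanged into ECF and co-expression ground truth
(independent genes co-express at the product of marginals). Default baseline
rates (π ~ Beta(1.5, 4) clipped to [0.02, 0.8]; NB mean ~ LogNormal(1.2,
0.5)) give cells a few hundred UMIs over a few hundred genes — deep enough
to pass the 200-UMI QC rule at realistic rates — and a random tenth of genes
a 3-fold boost in one cell type so HVG selection has structure. Mitochondrial
content is emulated by naming the first ⌈2 %⌉ of genes `MT-…`. Not emulated:
gene–gene correlation beyond cell-type structure, doublets, ambient RNA.
Passing tests therefore demonstrate correct statistics under the stated
model, not robustness to those artifacts.

**Paired panel.** A latent positive state is drawn at the configured
prevalence; RNA scores are normal around θ* ± (separation/2)·σ (σ = 0.5,
clipped at 0), so the implied AUC is Φ(separation/√2) and the Youden optimum
is θ* itself. IHC percentages are positive iff the latent state is (Dirichlet
split of a uniform 10–100 % stained total); `h_score_noise` flips the IHC
call with the given probability, reproducing imperfect IHC/RNA concordance
of the published MUC1 case.

**Bulk cohort.** Per-gene positivity states are independent Bernoulli draws;
positive/negative samples express at N(4.0, 0.5)/N(0.5, 0.3) on the
log2(TPM+1) scale — well separated so that threshold recovery isolates the
calibration logic. Survival is exponential with baseline hazard 1/1000 per
day multiplied by the hazard ratio (default 2) for samples positive for both
anchor genes; censoring is independent exponential with its rate set so
that roughly the configured fraction of baseline-hazard samples is censored
(0 → all events, 1 → all censored).

All generators are bit-reproducible given their seed.

## Problem sizes and numerical conventions

The demo pipeline and the acceptance script run at desk scale, chosen so the
full suite completes in a couple of minutes on one CPU while every recovery
check retains adequate power: 1200-cell / 300-gene demo atlas with 100-tree
forests; screening recovery at 2000 cells × 500 genes with 100 trees, one
permutation repeat and a single `max_features` setting (the planted effect —
ECF 0.8 vs 0.05 — is far above the detection floor, so tree count does not
limit the check); 100-seed threshold recovery at n = 500; 1000-replicate
null calibrations of the rank-sum and log-rank tests. Library defaults keep
the published analysis values (1000 trees, 10-fold CV, 2000 HVGs, 30 PCs).
Floating-point contracts: exact assertions only where arithmetic is exact
(H-scores, printed-rate rounding); 1e−12 for oracle identities; 3 standard
errors for Monte-Carlo recoveries.

## Known limitations

* Malignant-cell identification, graph-based batch evaluation, and automatic
  reference annotation are out of scope; labels come in with the data.
* Co-localization of two markers is judged at sample level, not cell level —
  consecutive-section microscopy cannot be reproduced computationally.
* The Cox interface is univariate only; multivariate adjustment, time-varying
  covariates and competing risks are not implemented.
* Published PDX cut-offs are reference constants, not recomputed values.
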