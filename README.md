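# dualtaa

Screening and validation toolkit for **dual tumor-associated-antigen (TAA)
targeting** — the strategy of directing a therapy (bispecific antibody, ADC,
CAR-T) at *two* surface proteins so that tumor cells expressing both are hit
while normal tissues expressing at most one are spared. The package
implements, as a tested and reusable pipeline, the computational workflow
used to nominate and validate such a target pair (the motivating case is
EGFR + MUC1 in lung adenocarcinoma and colorectal cancer):

1. **Single-cell screening** (`sc_preprocess`, `taa_screen`): QC a
   multi-study tumor/normal UMI count atlas (cells with < 3 detected genes,
   < 200 UMIs or > 20 % mitochondrial counts removed), normalize each cell to
   10⁶ counts + log1p, select the top-2000 highly variable genes, embed with
   30-component PCA, regress out dataset-of-origin batch effects with ridge
   regression, then rank genes by how strongly they separate malignant from
   normal cells: a 1000-tree random forest (6:2:2 train/test/validation
   split, 10-fold CV model selection by AUC) scored by permutation importance
   (mean decrease in accuracy), intersected with a surfaceome list to yield
   the top-100 surface candidates. The **expressing cell fraction**
   ECF(g, group) = #{cells with raw count > 0} / #cells quantifies per-group
   expression.
2. **Co-expression specificity** (`coexpr`): per patient and per cell
   population, the fraction of cells with raw count > 0 for *both* the
   anchor (EGFR) and a candidate partner; partners are compared on malignant
   coverage vs stromal leakage, with a two-sided rank-sum test of malignant
   vs stromal fractions and a "share of patients above 10 % co-expression"
   summary.
3. **IHC quantification** (`ihc_scoring`): the H-score
   `H = 1·(%1+) + 2·(%2+) + 3·(%3+) ∈ [0, 300]`, nested expression tiers
   (positive H > 0, medium H ≥ 100, high H ≥ 200, boundaries inclusive),
   sample-level dual positivity (≥ 1 % of cells stained for both markers at
   any intensity) and cohort positivity rates.
4. **RNA threshold calibration** (`calibration`): from paired IHC + RNA-seq
   samples, an ROC curve of log2(TPM+1) against protein positivity
   (H-score > 0); AUC by the trapezoid rule (equals Mann–Whitney
   concordance); the operating cut-off θ chosen by Youden's
   J = max(TPR − FPR). Calibrated cut-offs applied to a bulk cohort give
   single- and dual-marker patient coverage. The published LUAD PDX
   calibration (θ = 2.23 for EGFR, 1.5 for MUC1) ships as a reference
   constant.
5. **Survival stratification** (`survival`): stage III/IV patients grouped as
   dual-high / mixed / dual-low by median split or calibrated thresholds;
   Kaplan–Meier product-limit curves, the log-rank test, and a univariate Cox
   model for hazard ratios.

All inputs can be produced by the built-in generators (`synthetic_data`) with
known ground truth: a zero-inflated (zero-truncated) negative-binomial
single-cell simulator with batch effects, a paired IHC–RNA panel with a
planted true threshold, and a bulk cohort with planted positivity fractions
and a planted hazard ratio. `pipeline.run_pipeline` chains everything into a
deterministic, digest-stamped report.

## Worked example

```bash
dualtaa run --seed 1 --outdir demo_run
```

runs the full demo (6 patients × 200 cells across 2 batches, 300 genes with
EGFR/MUC1/MET/ERBB3/TACSTD2 planted, a 200-sample paired panel per marker, a
600-sample cohort) and prints:

```json
{
  "config_hash": "261662605c0b885f",
  "seed": 1,
  "digest": "6c94ed06730db288b2573a831f1ff94979c4f2cd81b97e7ce637655db1663924"
}
```

with the full report in `demo_run/report.json`. Highlights of that report
(seed 1):

* `screen`: test AUC 0.981; EGFR ranks 1st and MUC1 2nd among all features —
  the planted tumor-restricted genes dominate the permutation importance.
* `coexpr`: MUC1 is the most tumor-specific partner
  (`malignant_vs_stromal_p ≈ 4.4e-07`); MET/TACSTD2 leak into stroma.
* `calibration`: EGFR AUC 0.977 with cut-off 2.19 (truth 2.23); MUC1 AUC
  0.978 with cut-off 1.62 (truth 1.50) — Youden recovers the planted
  thresholds.
* `coverage`: 86.3 % of cohort samples dual-positive (planted truth
  0.95 × 0.90 = 85.5 %).
* `survival`: dual-high patients (calibrated-threshold rule, stage III/IV)
  show log-rank χ² = 20.6, p ≈ 5.6e-06, Cox HR 2.49 [1.66, 3.74] against a
  planted hazard ratio of 2.

Every number above is computed at run time; rerunning with the same seed
reproduces the report digest bit-for-bit.

The same stages are available as individual subcommands
(`dualtaa simulate|qc|normalize|hvg|pca|batch-correct|annotate|screen|coexpr|ihc|calibrate|coverage|survive`)
operating on plain-text files (MTX + TSV, CSV, YAML), and as library
functions.

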