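"""Cross-modality threshold calibration and cohort coverage.

Paired IHC + RNA samples are used to calibrate, per marker, an RNA threshold
(in log2(TPM+1) units) that reproduces protein positivity: an ROC curve is
swept over midpoints of the observed RNA scores against the IHC-derived
binary labels, the AUC summarises concordance, and Youden's J = TPR - FPR
selects the operating threshold. The calibrated thresholds are then applied
to a bulk cohort to estimate single- and dual-marker positivity coverage.

The published reference calibration for the EGFR/MUC1 pair on lung
adenocarcinoma PDX material — log2(TPM+1) cut-offs 2.23 (EGFR, AUC 0.97) and
1.5 (MUC1, AUC 0.6) against H-score > 0 labels — is shipped as the constant
:data:`REFERENCE_CUTOFFS`. Those numbers are tied to that PDX panel and are
not recomputable from synthetic data; they are provided for applying the
published thresholds to new cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ihc_scoring import cohort_positivity_rate

__all__ = [
    "REFERENCE_CUTOFFS",
    "CalibrationResult",
    "CoverageEstimate",
    "tpm_from_counts",
    "log2p1",
    "roc_curve",
    "youden_threshold",
    "calibrate_marker",
    "apply_cutoffs",
]

#: Published reference calibration (LUAD PDX panel, H-score > 0 labels).
REFERENCE_CUTOFFS: dict[str, dict[str, float]] = {
    "EGFR": {"cutoff_log2_tpm1": 2.23, "auc": 0.97},
    "MUC1": {"cutoff_log2_tpm1": 1.5, "auc": 0.6},
}


def tpm_from_counts(counts, lengths) -> np.ndarray:
    """Transcripts-per-million from read counts and effective lengths.

    Accepts vectors (one sample) or matrices (genes x samples); TPM sums to
    1e6 per sample. All-zero samples are an error.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("effective lengths must be > 0")
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    if counts.ndim == 1:
        rate = counts / lengths
        total = rate.sum()
        if total == 0:
            raise ValueError("all-zero sample: TPM undefined")
        return rate / total * 1e6
    rate = counts / lengths[:, None]
    totals = rate.sum(axis=0)
    if np.any(totals == 0):
        bad = np.nonzero(totals == 0)[0]
        raise ValueError(f"all-zero sample(s) at column(s) {bad.tolist()}")
    return rate / totals[None, :] * 1e6


def log2p1(tpm) -> np.ndarray:
    """log2(TPM + 1), the expression scale thresholds are calibrated on."""
    return np.log2(np.asarray(tpm, dtype=float) + 1.0)


@dataclass
class CalibrationResult:
    """ROC curve, AUC and (once selected) the Youden operating point."""

    marker: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    youden_j: float | None = None
    cutoff: float | None = None
    roc_points: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.roc_points = pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_curve(scores, labels, marker: str = "") -> CalibrationResult:
    """ROC of continuous scores against binary labels.

    Candidate thresholds are +inf, the midpoints between adjacent unique
    scores, and -inf; a sample is called positive when score >= threshold.
    The curve therefore starts at (0, 0) and ends at (1, 1) and is monotone
    in both coordinates. AUC is computed by the trapezoid rule and equals the
    Mann-Whitney concordance probability with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both positive and negative labels")

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.array([])
    thresholds = np.concatenate(([np.inf], mids[::-1], [-np.inf]))
    # score >= thr, descending thresholds -> cumulative positives
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        called = scores >= thr
        tpr[i] = np.sum(called & (labels == 1)) / n_pos
        fpr[i] = np.sum(called & (labels == 0)) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return CalibrationResult(
        marker=marker, fpr=fpr, tpr=tpr, thresholds=thresholds,
        auc=auc, n_pos=n_pos, n_neg=n_neg,
    )


def youden_threshold(result: CalibrationResult) -> CalibrationResult:
    """Select the threshold maximizing Youden's J = TPR - FPR.

    Ties are broken by the smallest threshold (maximal sensitivity); the
    chosen cut-off is a midpoint between adjacent unique scores. When all
    scores are equal, J = 0 and the single score value is reported.
    """
    j = result.tpr - result.fpr
    finite = np.isfinite(result.thresholds)
    if not finite.any():  # all scores identical: only the +/-inf endpoints
        result.youden_j = 0.0
        result.cutoff = float("nan")
        return result
    j_f = j[finite]
    thr_f = result.thresholds[finite]
    best_j = j_f.max()
    if best_j <= 0:
        # uninformative ROC: fall back to the smallest candidate threshold
        result.youden_j = float(max(best_j, 0.0))
        result.cutoff = float(thr_f.min())
        return result
    candidates = thr_f[j_f == best_j]
    result.youden_j = float(best_j)
    result.cutoff = float(candidates.min())
    return result


def calibrate_marker(panel: pd.DataFrame, marker: str | None = None) -> CalibrationResult:
    """Full calibration from a paired panel table.

    ``panel`` needs columns ``pct_1plus``, ``pct_2plus``, ``pct_3plus`` and
    ``log2_tpm1``; the IHC label is protein positivity, H-score > 0.
    """
    hs = (
        panel["pct_1plus"] + 2 * panel["pct_2plus"] + 3 * panel["pct_3plus"]
    ).to_numpy()
    labels = (hs > 0).astype(int)
    name = marker or (str(panel["marker"].iloc[0]) if "marker" in panel else "")
    return youden_threshold(roc_curve(panel["log2_tpm1"].to_numpy(), labels, name))


@dataclass
class CoverageEstimate:
    """Single- and dual-marker positivity of a cohort at given thresholds."""

    per_marker: pd.DataFrame  # marker, n_pos, n_total, pct, threshold
    dual_n_pos: int
    n_total: int
    dual_pct: float
    thresholds: dict[str, float]


def apply_cutoffs(expression: pd.DataFrame, thresholds: dict[str, float]) -> CoverageEstimate:
    """Call positivity per marker (score >= threshold, closed boundary) and
    estimate dual coverage (positive for every thresholded marker).

    ``expression`` is samples x genes on the log2(TPM+1) scale. Percentages
    use the same half-up one-decimal rounding as IHC cohort rates.
    """
    missing = [m for m in thresholds if m not in expression.columns]
    if missing:
        raise KeyError(f"markers absent from expression table: {missing}")
    rows = []
    dual = np.ones(len(expression), dtype=bool)
    for marker, theta in thresholds.items():
        calls = expression[marker].to_numpy() >= theta
        dual &= calls
        n_pos, n_total, pct = cohort_positivity_rate(calls)
        rows.append(
            {"marker": marker, "n_pos": n_pos, "n_total": n_total,
             "pct": pct, "threshold": theta}
        )
    dual_n, n_total, dual_pct = cohort_positivity_rate(dual)
    return CoverageEstimate(
        per_marker=pd.DataFrame(rows),
        dual_n_pos=dual_n,
        n_total=n_total,
        dual_pct=dual_pct,
        thresholds=dict(thresholds),
    )
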