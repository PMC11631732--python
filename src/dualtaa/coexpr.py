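"""Binary co-expression fractions and tumor-vs-stroma specificity tests.

Co-expression of an anchor gene (e.g. EGFR) with a candidate partner is
scored per patient and per cell group as the fraction of cells in which both
genes have raw count > 0. Candidate partners are compared on two views: how
often malignant cells co-express the pair (coverage) and how rarely stromal
cells do (specificity). A rank-sum test compares per-patient malignant
fractions against per-(patient, stromal group) fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .taa_screen import _raw_counts

__all__ = [
    "CoexprRecord",
    "coexpression_fraction",
    "coexpression_table",
    "patient_threshold_summary",
    "compare_malignant_vs_stromal",
    "partner_screen",
    "DEFAULT_PARTNERS",
]

#: Partners under active drug development that the anchor is compared against.
DEFAULT_PARTNERS = ["MUC1", "MET", "ERBB3", "TACSTD2"]


@dataclass
class CoexprRecord:
    """Dual-expression fraction of (anchor, partner) in one patient group."""

    patient: str
    group: str
    anchor: str
    partner: str
    n_cells: int
    n_dual: int

    @property
    def fraction(self) -> float:
        return self.n_dual / self.n_cells if self.n_cells else float("nan")


def coexpression_fraction(
    adata: ad.AnnData, anchor: str, partner: str, mask, patient: str = "", group: str = ""
) -> CoexprRecord:
    """Fraction of masked cells with raw count > 0 for both genes.

    An empty cell set yields a record with ``n_cells == 0`` (flagged by NaN
    fraction) rather than an error, so callers can exclude it downstream.
    """
    for g in (anchor, partner):
        if g not in adata.var_names:
            raise KeyError(f"gene {g!r} not in matrix")
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        return CoexprRecord(patient, group, anchor, partner, 0, 0)
    X = _raw_counts(adata)
    a = np.asarray((X[:, adata.var_names.get_loc(anchor)] > 0).todense()).ravel()
    b = np.asarray((X[:, adata.var_names.get_loc(partner)] > 0).todense()).ravel()
    n_dual = int(np.sum(a[mask] & b[mask]))
    return CoexprRecord(patient, group, anchor, partner, n, n_dual)


def coexpression_table(
    adata: ad.AnnData,
    anchor: str,
    partner: str,
    patient_col: str = "patient",
    group_col: str = "cell_type",
    min_cells: int = 10,
) -> pd.DataFrame:
    """Per-(patient, cell group) co-expression fractions as a DataFrame.

    Groups with fewer than ``min_cells`` cells are kept in the table but
    flagged ``valid=False`` and excluded from downstream tests — fraction
    estimates from a handful of cells are too unstable to compare.
    """
    rows = []
    obs = adata.obs
    for (pat, grp), idx in obs.groupby([patient_col, group_col], observed=True).groups.items():
        mask = obs.index.isin(idx)
        rec = coexpression_fraction(adata, anchor, partner, mask, str(pat), str(grp))
        rows.append(
            {
                "patient": rec.patient,
                "group": rec.group,
                "anchor": anchor,
                "partner": partner,
                "n_cells": rec.n_cells,
                "n_dual": rec.n_dual,
                "fraction": rec.fraction,
                "valid": rec.n_cells >= min_cells,
            }
        )
    return pd.DataFrame(rows)


def patient_threshold_summary(
    records: pd.DataFrame, threshold: float = 0.10
) -> pd.Series:
    """Per cell group: the share of patients with co-expression > threshold.

    Strict inequality: a patient exactly at the threshold does not count.
    Only valid records (enough cells) participate.
    """
    valid = records[records.get("valid", True)]
    if valid.empty:
        raise ValueError("no valid co-expression records")
    return valid.groupby("group", observed=True)["fraction"].apply(
        lambda f: float((f > threshold).mean())
    )


def compare_malignant_vs_stromal(
    records: pd.DataFrame, malignant_group: str = "malignant"
) -> dict:
    """Two-sided rank-sum test: malignant vs stromal co-expression fractions.

    One observation per patient on the malignant side; one per
    (patient, stromal group) on the stromal side. Exact null distribution is
    used when both sides have <= 12 observations and no ties; otherwise the
    normal approximation with tie correction.
    """
    valid = records[records.get("valid", True)]
    mal = valid.loc[valid["group"] == malignant_group, "fraction"].to_numpy()
    stro = valid.loc[valid["group"] != malignant_group, "fraction"].to_numpy()
    if len(mal) < 2 or len(stro) < 2:
        raise ValueError("need at least 2 observations per side")
    has_ties = len(np.unique(np.concatenate([mal, stro]))) < len(mal) + len(stro)
    method = "exact" if (len(mal) <= 12 and len(stro) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(mal, stro, alternative="two-sided", method=method)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "method": method,
        "median_malignant": float(np.median(mal)),
        "median_stromal": float(np.median(stro)),
        "n_malignant": len(mal),
        "n_stromal": len(stro),
    }


def partner_screen(
    adata: ad.AnnData,
    anchor: str,
    partners: list[str] | None = None,
    threshold: float = 0.10,
    malignant_group: str = "malignant",
    patient_col: str = "patient",
    group_col: str = "cell_type",
    min_cells: int = 10,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Score each candidate partner for coverage and tumor specificity.

    Returns the per-partner record tables and a summary with, per partner,
    the median malignant fraction (coverage view), the maximum stromal
    fraction (specificity view: lower is safer), and the share of patients
    above the co-expression threshold in malignant cells. Partners are ranked
    by descending malignant median and, as specificity ranking, ascending
    stromal maximum. Missing partner genes are skipped with a warning.
    """
    partners = DEFAULT_PARTNERS if partners is None else partners
    tables: dict[str, pd.DataFrame] = {}
    rows = []
    for partner in partners:
        if partner not in adata.var_names:
            warnings.warn(f"partner gene {partner!r} absent; skipped")
            continue
        tab = coexpression_table(
            adata, anchor, partner, patient_col, group_col, min_cells
        )
        tables[partner] = tab
        valid = tab[tab["valid"]]
        mal = valid[valid["group"] == malignant_group]["fraction"]
        stro = valid[valid["group"] != malignant_group]["fraction"]
        rows.append(
            {
                "partner": partner,
                "malignant_median": float(mal.median()) if len(mal) else np.nan,
                "stromal_max": float(stro.max()) if len(stro) else np.nan,
                "patients_above_threshold": float((mal > threshold).mean())
                if len(mal)
                else np.nan,
            }
        )
    summary = pd.DataFrame(rows)
    if not summary.empty:
        summary["coverage_rank"] = (
            summary["malignant_median"].rank(ascending=False, method="min").astype(int)
        )
        summary["specificity_rank"] = (
            summary["stromal_max"].rank(ascending=True, method="min").astype(int)
        )
    return tables, summary
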