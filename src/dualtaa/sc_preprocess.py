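"""Single-cell preprocessing: QC, normalization, HVG, PCA, batch regression.

The processing chain mirrors a standard scRNA-seq workflow: cells are removed
when they have fewer than 3 detected genes, fewer than 200 UMIs, or more than
20% mitochondrial counts; surviving cells are scaled to a fixed per-cell total
(1e6 by default) and log1p-transformed; the top 2000 genes by mean-binned
normalized dispersion feed a 30-component PCA; dataset-of-origin effects are
removed by ridge regression on one-hot batch indicators. A marker-score
annotator assigns cell types from curated marker sets.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

__all__ = [
    "QCThresholds",
    "QCReport",
    "PCAResult",
    "qc_filter",
    "normalize_log",
    "select_hvg",
    "pca_embed",
    "regress_batch",
    "annotate_by_markers",
]

MITO_REGEX_DEFAULT = r"^MT-"


@dataclass
class QCThresholds:
    """Cell-level QC cut-offs; a cell is kept only if it passes all three."""

    min_genes_detected: int = 3
    min_umi: int = 200
    max_mito_fraction: float = 0.20
    mito_regex: str = MITO_REGEX_DEFAULT

    def validate(self) -> None:
        if self.min_genes_detected < 0 or self.min_umi < 0:
            raise ValueError("QC thresholds must be non-negative")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class QCReport:
    n_input: int
    removed_low_genes: int
    removed_low_umi: int
    removed_high_mito: int
    removed_total: int
    n_retained: int
    warnings: list[str] = field(default_factory=list)


def _cell_stats(adata: ad.AnnData, mito_regex: str) -> pd.DataFrame:
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    n_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    pat = re.compile(mito_regex, re.IGNORECASE)
    mito_mask = np.array([bool(pat.search(g)) for g in adata.var_names])
    mito_total = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "n_genes_detected": n_detected.astype(int),
            "total_umi": total.astype(int),
            "mito_fraction": mito_frac,
        },
        index=adata.obs_names,
    )


def qc_filter(
    adata: ad.AnnData, thresholds: QCThresholds | None = None
) -> tuple[ad.AnnData, QCReport]:
    """Remove low-quality cells and report per-rule removal counts.

    A cell is removed if it has fewer than ``min_genes_detected`` detected
    genes, fewer than ``min_umi`` total counts, or a mitochondrial fraction
    strictly greater than ``max_mito_fraction``. Mitochondrial genes are
    identified by symbol regex (``MT-`` prefix, case-insensitive, by default).
    An empty result is reported as a warning, not an exception.
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    stats = _cell_stats(adata, thresholds.mito_regex)
    fail_genes = stats["n_genes_detected"] < thresholds.min_genes_detected
    fail_umi = stats["total_umi"] < thresholds.min_umi
    fail_mito = stats["mito_fraction"] > thresholds.max_mito_fraction
    keep = ~(fail_genes | fail_umi | fail_mito)

    out = adata[keep.values].copy()
    out.obs[stats.columns] = stats.loc[keep.values]
    report = QCReport(
        n_input=adata.n_obs,
        removed_low_genes=int(fail_genes.sum()),
        removed_low_umi=int(fail_umi.sum()),
        removed_high_mito=int(fail_mito.sum()),
        removed_total=int((~keep).sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        report.warnings.append("no cells remain after QC filtering")
    return out, report


def normalize_log(adata: ad.AnnData, scale: float = 1e6) -> ad.AnnData:
    """Scale each cell to ``scale`` total counts, then log1p-transform.

    Raw counts are preserved in ``layers['counts']``; the normalization scale
    and log base (natural log via log1p) are recorded in ``uns``. Cells with
    zero total counts are rejected by name — they should have been removed by
    QC.
    """
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        names = ", ".join(adata.obs_names[zero[:5]])
        raise ValueError(f"cells with zero total counts: {names}")
    norm = X.astype(float).multiply(scale / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out = ad.AnnData(X=norm, obs=adata.obs.copy(), var=adata.var.copy(), uns=dict(adata.uns))
    out.layers["counts"] = X.copy()
    out.uns["normalization"] = {"scale": scale, "log": "log1p (natural)"}
    return out


def select_hvg(norm: ad.AnnData, k: int = 2000, n_bins: int = 20) -> list[str]:
    """Select the top-``k`` highly variable genes by normalized dispersion.

    Dispersion is variance/mean of the pre-log normalized values (counts per
    ``scale``), z-scored within ``n_bins`` equal-frequency bins of the mean;
    zero-dispersion genes are never selected while variable genes remain.
    Ties break deterministically by gene symbol. Also writes ``hvg`` (bool)
    and ``dispersion_norm`` columns into ``norm.var``.
    """
    if k > norm.n_vars:
        raise ValueError(f"k={k} exceeds number of genes ({norm.n_vars})")
    X = norm.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    pre = X.copy()
    pre.data = np.expm1(pre.data)  # back to the pre-log normalized scale
    n = pre.shape[0]
    mean = np.asarray(pre.mean(axis=0)).ravel()
    sq = pre.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = np.maximum(ex2 - mean**2, 0.0) * (n / max(n - 1, 1))
    var[var <= 1e-12 * np.maximum(ex2, 1.0)] = 0.0  # cancellation noise
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)

    df = pd.DataFrame({"mean": mean, "disp": disp}, index=norm.var_names)
    expressed = df["mean"] > 0
    df["bin"] = -1
    if expressed.any():
        df.loc[expressed, "bin"] = pd.qcut(
            df.loc[expressed, "mean"], q=min(n_bins, int(expressed.sum())),
            labels=False, duplicates="drop",
        )
    z = np.full(len(df), -np.inf)
    for b, grp in df[df["bin"] >= 0].groupby("bin"):
        mu, sd = grp["disp"].mean(), grp["disp"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            zb = np.zeros(len(grp))
        else:
            zb = (grp["disp"] - mu) / sd
        z[df.index.get_indexer(grp.index)] = zb
    z[disp == 0] = -np.inf  # invariant genes can never be "variable"
    df["z"] = z

    # stable sort on symbol first, then z: deterministic symbol tie-break
    ranked = df.sort_index(kind="mergesort").sort_values(
        "z", ascending=False, kind="mergesort"
    )
    top = list(ranked.index[:k])
    norm.var["dispersion_norm"] = df["z"].replace(-np.inf, np.nan)
    norm.var["hvg"] = norm.var_names.isin(top)
    return top


@dataclass
class PCAResult:
    embedding: np.ndarray            # cells x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    components: np.ndarray           # components x genes
    mean: np.ndarray
    gene_names: list[str]


def pca_embed(
    norm: ad.AnnData, genes: list[str] | None = None, n_components: int = 30
) -> PCAResult:
    """PCA of the (gene-centered) normalized matrix over the given genes.

    Components are ordered by non-increasing explained variance. If the input
    has fewer dimensions than requested, the embedding is truncated with a
    warning.
    """
    sub = norm[:, genes] if genes is not None else norm
    X = sub.X
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    max_comp = min(X.shape[0] - 1 if X.shape[0] > 1 else 1, X.shape[1])
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} reduced to {max_comp} (input rank limit)"
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    emb = pca.fit_transform(X)
    return PCAResult(
        embedding=emb,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        components=pca.components_,
        mean=pca.mean_,
        gene_names=list(sub.var_names),
    )


def regress_batch(
    matrix: np.ndarray, batches, ridge_lambda: float = 1.0
) -> np.ndarray:
    """Remove per-batch offsets from each feature by ridge regression.

    For each feature (column), the feature is centered and regressed on
    one-hot batch indicators with an L2 penalty ``ridge_lambda``; the fitted
    batch effects, recentred to mean zero across cells, are subtracted. With
    ``ridge_lambda -> 0`` the corrected per-batch feature means coincide; the
    global feature mean is always preserved. A single batch is returned
    unchanged with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    batches = np.asarray(batches)
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")
    levels, inv = np.unique(batches, return_inverse=True)
    if len(levels) < 2:
        warnings.warn("single batch: batch regression is the identity")
        return X.copy()
    n = X.shape[0]
    n_b = np.bincount(inv, minlength=len(levels)).astype(float)
    grand = X.mean(axis=0, keepdims=True)
    centered = X - grand
    # Ridge on one-hot indicators has the closed form
    # beta_b = n_b * mean_b / (n_b + lambda) per feature.
    sums = np.zeros((len(levels), X.shape[1]))
    np.add.at(sums, inv, centered)
    beta = sums / (n_b[:, None] + ridge_lambda)
    fitted = beta[inv]
    fitted -= fitted.mean(axis=0, keepdims=True)  # keep global mean intact
    return X - fitted


def annotate_by_markers(
    norm: ad.AnnData,
    marker_sets: dict[str, list[str]],
    layer: str | None = None,
) -> pd.DataFrame:
    """Assign each cell the type whose marker set scores highest.

    The score of a type is the mean normalized expression of its marker genes
    in the cell. Ties break by the declared order of ``marker_sets``; cells
    with all scores zero are labelled ``unassigned``. Returns a DataFrame with
    ``label``, ``score`` (winning score) and ``margin`` (gap to runner-up).
    """
    if not marker_sets or any(len(v) == 0 for v in marker_sets.values()):
        raise ValueError("marker sets must be non-empty")
    missing = {
        t: [g for g in genes if g not in norm.var_names]
        for t, genes in marker_sets.items()
    }
    missing = {t: g for t, g in missing.items() if g}
    if missing:
        raise ValueError(f"marker genes absent from matrix: {missing}")

    X = norm.layers[layer] if layer else norm.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    types = list(marker_sets)
    scores = np.zeros((norm.n_obs, len(types)))
    for j, t in enumerate(types):
        idx = norm.var_names.get_indexer(marker_sets[t])
        scores[:, j] = np.asarray(X[:, idx].mean(axis=1)).ravel()
    best = scores.argmax(axis=1)  # argmax takes the first max: declared order
    labels = np.array(types, dtype=object)[best]
    top = scores[np.arange(len(best)), best]
    runner = np.partition(scores, -2, axis=1)[:, -2] if len(types) > 1 else np.zeros_like(top)
    labels[top == 0] = "unassigned"
    return pd.DataFrame(
        {"label": labels, "score": top, "margin": top - runner},
        index=norm.obs_names,
    )
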