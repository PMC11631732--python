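"""Tumor-vs-normal gene ranking and the expressing-cell-fraction statistic.

The screen trains a random-forest classifier to separate malignant from
normal cells on their expression profiles, ranks genes by permutation
importance (mean decrease in accuracy on held-out cells), and intersects the
ranking with a cell-surface protein list to yield candidate antigen targets.
The expressing cell fraction (ECF) of a gene in a cell group is the fraction
of cells with raw count > 0 — it is deliberately defined on raw counts and is
therefore invariant to normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ECFRecord",
    "expressing_cell_fraction",
    "rank_features",
    "intersect_surfaceome",
    "read_surfaceome",
]


@dataclass
class ECFRecord:
    """Expressing cell fraction of one gene in one cell group."""

    gene: str
    group: str
    n_cells: int
    n_expressing: int

    @property
    def ecf(self) -> float:
        return self.n_expressing / self.n_cells


def _raw_counts(adata: ad.AnnData) -> sp.csr_matrix:
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    return X if sp.issparse(X) else sp.csr_matrix(X)


def expressing_cell_fraction(
    adata: ad.AnnData, gene: str, mask, group: str = ""
) -> ECFRecord:
    """ECF of ``gene`` over the cells selected by boolean ``mask``.

    Raw counts are used (``layers['counts']`` when present, else ``X``);
    a count > 0 marks a cell as expressing. Empty groups are an error.
    """
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not in matrix")
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"empty cell group {group!r}")
    col = _raw_counts(adata)[:, adata.var_names.get_loc(gene)]
    expressing = int((col[mask] > 0).sum())
    return ECFRecord(gene=gene, group=group, n_cells=n, n_expressing=expressing)


def _split_indices(
    labels: np.ndarray, split: tuple[float, float, float], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/test/validation split at the given ratios."""
    if not np.isclose(sum(split), 1.0):
        raise ValueError("split ratios must sum to 1")
    train, test, val = [], [], []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        rng.shuffle(idx)
        n = len(idx)
        n_tr = int(round(split[0] * n))
        n_te = int(round(split[1] * n))
        train.append(idx[:n_tr])
        test.append(idx[n_tr : n_tr + n_te])
        val.append(idx[n_tr + n_te :])
    return (
        np.sort(np.concatenate(train)),
        np.sort(np.concatenate(test)),
        np.sort(np.concatenate(val)),
    )


def _mean_decrease_accuracy(
    model: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_repeats: int = 1,
    chunk: int = 64,
) -> np.ndarray:
    """Permutation importance: drop in held-out accuracy when a feature is
    shuffled. Permuted copies are batched into one predict call per chunk of
    features, which is much faster than per-feature prediction."""
    base = (model.predict(X) == y).mean()
    n, p = X.shape
    imp = np.zeros(p)
    for _ in range(n_repeats):
        for start in range(0, p, chunk):
            feats = range(start, min(start + chunk, p))
            stacked = np.repeat(X[None, :, :], len(list(feats)), axis=0).copy()
            for k, j in enumerate(feats):
                stacked[k, :, j] = X[rng.permutation(n), j]
            preds = model.predict(stacked.reshape(-1, p)).reshape(len(stacked), n)
            acc = (preds == y[None, :]).mean(axis=1)
            imp[start : start + len(stacked)] += base - acc
    return imp / n_repeats


def rank_features(
    data,
    labels,
    genes: list[str] | None = None,
    n_trees: int = 1000,
    split: tuple[float, float, float] = (0.6, 0.2, 0.2),
    cv_folds: int = 10,
    n_repeats: int = 1,
    param_grid: list[dict] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank genes by their importance in separating tumor from normal cells.

    Cells are split 6:2:2 (stratified) into training, testing and validation
    sets. Candidate forest settings are compared by mean AUC under
    ``cv_folds``-fold cross-validation on the training split; the winner is
    refit on the full training split, its test-split AUC recorded, and gene
    importances computed as mean decrease in accuracy on the test split.
    Negative importances are kept as-is.

    Parameters
    ----------
    data : AnnData or array (cells x genes)
        Expression features; normalized values are the intended input.
    labels : array-like of {"tumor", "normal"} (or any two classes)

    Returns
    -------
    DataFrame with columns ``gene``, ``importance``, ``rank``, sorted by
    importance descending; ``attrs`` carries ``test_auc``, ``validation_auc``,
    ``cv_auc``, ``best_params`` and ``seed``.
    """
    if isinstance(data, ad.AnnData):
        X = data.X.toarray() if sp.issparse(data.X) else np.asarray(data.X)
        genes = list(data.var_names) if genes is None else genes
    else:
        X = np.asarray(data, dtype=float)
        if genes is None:
            genes = [f"g{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("rank_features requires exactly two classes")
    y_bin = (y == classes[1]).astype(int)

    rng = np.random.default_rng(seed)
    tr, te, va = _split_indices(y_bin, split, rng)
    if param_grid is None:
        param_grid = [{"max_features": "sqrt"}, {"max_features": 0.2}]

    cv_scores = []
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for params in param_grid:
        aucs = []
        for fit_idx, hold_idx in skf.split(X[tr], y_bin[tr]):
            m = RandomForestClassifier(
                n_estimators=max(50, n_trees // 5),  # lighter forests for CV
                random_state=seed,
                n_jobs=1,
                **params,
            )
            m.fit(X[tr][fit_idx], y_bin[tr][fit_idx])
            prob = m.predict_proba(X[tr][hold_idx])[:, 1]
            aucs.append(roc_auc_score(y_bin[tr][hold_idx], prob))
        cv_scores.append(float(np.mean(aucs)))
    best = int(np.argmax(cv_scores))

    model = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1, **param_grid[best]
    )
    model.fit(X[tr], y_bin[tr])
    test_auc = float(roc_auc_score(y_bin[te], model.predict_proba(X[te])[:, 1]))
    val_auc = float(roc_auc_score(y_bin[va], model.predict_proba(X[va])[:, 1]))
    importance = _mean_decrease_accuracy(model, X[te], y_bin[te], rng, n_repeats)

    table = pd.DataFrame({"gene": genes, "importance": importance})
    table = table.sort_values(
        ["importance", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table.attrs.update(
        {
            "test_auc": test_auc,
            "validation_auc": val_auc,
            "cv_auc": cv_scores[best],
            "best_params": param_grid[best],
            "seed": seed,
            "classes": list(map(str, classes)),
        }
    )
    return table


def intersect_surfaceome(
    ranking: pd.DataFrame, surface_list, top_k: int = 100
) -> list[str]:
    """Keep surface genes, then take the ``top_k`` by importance.

    Rank-then-filter semantics: the ranking is filtered to surfaceome
    membership and truncated. Fewer than ``top_k`` genes (or none) trigger a
    warning, not an error.
    """
    surface = set(surface_list)
    if not surface:
        raise ValueError("surface_list must be non-empty")
    hits = ranking[ranking["gene"].isin(surface)]
    if hits.empty:
        warnings.warn("no ranked genes are on the surfaceome list")
        return []
    if len(hits) < top_k:
        warnings.warn(
            f"only {len(hits)} surface genes available (requested {top_k})"
        )
    return list(hits.nsmallest(top_k, "rank")["gene"])


def read_surfaceome(path) -> list[str]:
    """Read a surfaceome list: one gene symbol per line, '#' comments."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
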