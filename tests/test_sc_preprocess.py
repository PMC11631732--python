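"""QC, normalization, HVG selection, PCA and batch regression."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from dualtaa import sc_preprocess as pp
from dualtaa import synthetic_data as sd


def _adata(counts, gene_names=None, obs=None):
    counts = np.asarray(counts)
    gene_names = gene_names or [f"G{i}" for i in range(counts.shape[1])]
    a = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=obs if obs is not None else pd.DataFrame(index=[f"c{i}" for i in range(counts.shape[0])]),
        var=pd.DataFrame(index=gene_names),
    )
    return a


class TestQC:
    def test_rule_boundaries(self):
        # one cell per rule boundary: genes 2 vs 3, UMI 199 vs 200, mito 20 vs 21%
        genes = ["MT-G0"] + [f"G{i}" for i in range(9)]
        rows = [
            [0, 250, 250, 0, 0, 0, 0, 0, 0, 0],      # 2 genes, 500 UMI -> removed
            [0, 100, 100, 100, 0, 0, 0, 0, 0, 0],    # 3 genes -> kept
            [0, 66, 66, 67, 0, 0, 0, 0, 0, 0],       # 199 UMI -> removed
            [0, 66, 67, 67, 0, 0, 0, 0, 0, 0],       # 200 UMI -> kept
            [42, 53, 53, 52, 0, 0, 0, 0, 0, 0],      # 21% mito -> removed
            [40, 60, 50, 50, 0, 0, 0, 0, 0, 0],      # exactly 20% mito -> kept
        ]
        adata = _adata(rows, gene_names=genes)
        out, report = pp.qc_filter(adata)
        assert list(out.obs_names) == ["c1", "c3", "c5"]
        assert report.removed_low_genes == 1
        assert report.removed_low_umi == 1
        assert report.removed_high_mito == 1
        assert report.n_retained == 3

    def test_idempotent(self, tumor_normal_adata):
        once, r1 = pp.qc_filter(tumor_normal_adata)
        twice, r2 = pp.qc_filter(once)
        assert r2.removed_total == 0
        assert twice.n_obs == once.n_obs

    def test_empty_result_warns_not_raises(self):
        adata = _adata([[1, 0], [0, 1]])  # every cell has 1 gene < 3
        out, report = pp.qc_filter(adata)
        assert out.n_obs == 0
        assert report.warnings


class TestNormalize:
    @pytest.mark.parametrize(
        "counts, expected_prelog",
        [([1, 1], [5e5, 5e5]), ([3, 1], [7.5e5, 2.5e5])],
    )
    def test_proportional_scaling(self, counts, expected_prelog):
        norm = pp.normalize_log(_adata([counts]))
        vals = np.expm1(norm.X.toarray()[0])
        assert np.allclose(vals, expected_prelog)

    def test_zero_pattern_preserved(self, tumor_normal_adata):
        filtered, _ = pp.qc_filter(tumor_normal_adata)
        norm = pp.normalize_log(filtered)
        raw = filtered.X
        assert ((norm.X != 0).toarray() == (raw != 0).toarray()).all()

    def test_zero_total_cell_named_in_error(self):
        adata = _adata([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="c1"):
            pp.normalize_log(adata)

    def test_per_cell_totals_equal_scale(self):
        rngmat = np.random.default_rng(0).poisson(3, size=(10, 20)) + 1
        norm = pp.normalize_log(_adata(rngmat), scale=1e4)
        totals = np.expm1(norm.X.toarray()).sum(axis=1)
        assert np.allclose(totals, 1e4)


class TestHVG:
    def test_constant_gene_never_selected(self):
        # equalize depths so gene 0 is exactly constant after normalization
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, size=(100, 10))
        counts[:, 0] = 5
        filler = counts.sum(axis=1).max() + 10 - counts.sum(axis=1)
        counts = np.column_stack([counts, filler])
        norm = pp.normalize_log(_adata(counts))
        top = pp.select_hvg(norm, k=5)
        assert "G0" not in top

    def test_k_equals_n_genes_returns_all(self):
        counts = np.random.default_rng(2).poisson(3, size=(50, 8)) + 1
        norm = pp.normalize_log(_adata(counts))
        assert sorted(pp.select_hvg(norm, k=8)) == [f"G{i}" for i in range(8)]

    def test_k_too_large_raises(self):
        norm = pp.normalize_log(_adata([[1, 2], [2, 1]]))
        with pytest.raises(ValueError):
            pp.select_hvg(norm, k=3)

    def test_planted_differential_gene_outranks_noise(self):
        # two populations; one gene differs between them, the rest are i.i.d.
        n_genes, n_cells = 60, 2000
        pi = np.full((n_genes, len(sd.CELL_TYPES)), 0.3)
        lam = np.full((n_genes, len(sd.CELL_TYPES)), 3.0)
        pi[0, 0], lam[0, 0] = 0.9, 12.0  # strongly up in malignant cells
        cfg = sd.SCSimConfig(
            n_genes=n_genes, n_patients=4, n_datasets=1, cells_per_patient=500,
            cell_type_proportions={t: (0.5 if t in ("malignant", "T") else 0.0)
                                   for t in sd.CELL_TYPES},
            pi=pi, lam=lam, mito_gene_fraction=0.0, batch_effect_scale=0.0,
            seed=21,
        )
        norm = pp.normalize_log(sd.simulate_sc_cohort(cfg))
        top = pp.select_hvg(norm, k=5)
        assert norm.var_names[0] in top


class TestPCA:
    def test_explained_variance_non_increasing(self, tumor_normal_adata):
        norm = pp.normalize_log(tumor_normal_adata)
        res = pp.pca_embed(norm, n_components=10)
        assert np.all(np.diff(res.explained_variance) <= 1e-9)

    def test_rank_two_data_has_two_components(self):
        rng = np.random.default_rng(3)
        basis = rng.normal(size=(2, 30))
        coef = rng.normal(size=(100, 2))
        X = coef @ basis
        a = ad.AnnData(X=X)
        with pytest.warns(UserWarning):
            res = pp.pca_embed(a, n_components=50)  # rank-limited
        total = res.explained_variance.sum()
        assert res.explained_variance[2:].sum() <= 1e-8 * total

    def test_full_reconstruction(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 6))
        res = pp.pca_embed(ad.AnnData(X=X), n_components=6)
        recon = res.embedding @ res.components + res.mean
        assert np.allclose(recon, X, atol=1e-10)


class TestBatchRegression:
    def test_exact_offset_removal_at_lambda_zero(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 4))
        batches = np.array(["a"] * 100 + ["b"] * 100)
        X[100:] += 3.0  # constant offset on every feature
        corrected = pp.regress_batch(X, batches, ridge_lambda=0.0)
        means_a = corrected[:100].mean(axis=0)
        means_b = corrected[100:].mean(axis=0)
        assert np.allclose(means_a, means_b, atol=1e-10)

    def test_huge_penalty_approaches_identity(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 3))
        batches = np.array(["a"] * 25 + ["b"] * 25)
        corrected = pp.regress_batch(X, batches, ridge_lambda=1e6)
        assert np.allclose(corrected, X, atol=1e-3)

    def test_global_mean_preserved(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(90, 5))
        batches = rng.choice(["a", "b", "c"], size=90)
        corrected = pp.regress_batch(X, batches, ridge_lambda=1.0)
        assert np.allclose(corrected.mean(axis=0), X.mean(axis=0), atol=1e-10)

    def test_single_batch_is_identity_with_warning(self):
        X = np.ones((10, 2))
        with pytest.warns(UserWarning):
            out = pp.regress_batch(X, ["a"] * 10)
        assert np.array_equal(out, X)


class TestAnnotate:
    def test_sole_signal_wins(self):
        counts = np.array([[0, 0, 5, 5]])
        a = _adata(counts, gene_names=["EPCAM", "KRT8", "CD3D", "CD3E"])
        norm = pp.normalize_log(a)
        labels = pp.annotate_by_markers(
            norm, {"epithelial": ["EPCAM", "KRT8"], "T": ["CD3D", "CD3E"]}
        )
        assert labels["label"].iloc[0] == "T"

    def test_all_zero_scores_unassigned(self):
        counts = np.array([[0, 0, 1]])
        a = _adata(counts, gene_names=["EPCAM", "CD3D", "OTHER"])
        norm = pp.normalize_log(a)
        labels = pp.annotate_by_markers(norm, {"epithelial": ["EPCAM"], "T": ["CD3D"]})
        assert labels["label"].iloc[0] == "unassigned"

    def test_empty_marker_set_rejected(self, tumor_normal_adata):
        norm = pp.normalize_log(pp.qc_filter(tumor_normal_adata)[0])
        with pytest.raises(ValueError):
            pp.annotate_by_markers(norm, {"T": []})

    def test_accuracy_on_simulated_types(self):
        # marker means >= 4-fold above background -> near-perfect recovery
        planted = {
            "EPCAM_T": {"malignant": (0.9, 8.0)},
            "KRT_T": {"malignant": (0.9, 8.0)},
            "CD3_T": {"T": (0.9, 8.0)},
            "CD2_T": {"T": (0.9, 8.0)},
            "COL1_T": {"fibroblast": (0.9, 8.0)},
            "COL3_T": {"fibroblast": (0.9, 8.0)},
        }
        pi = np.full((40, len(sd.CELL_TYPES)), 0.2)
        lam = np.full((40, len(sd.CELL_TYPES)), 1.0)
        pi[:6] = 0.05  # marker genes are rare outside their own type
        lam[:6] = 0.5
        cfg = sd.SCSimConfig(
            n_genes=40, n_patients=3, n_datasets=1, cells_per_patient=300,
            cell_type_proportions={t: ({"malignant": 0.4, "T": 0.3, "fibroblast": 0.3}.get(t, 0.0))
                                   for t in sd.CELL_TYPES},
            pi=pi, lam=lam, planted=planted, mito_gene_fraction=0.0, seed=8,
        )
        adata = sd.simulate_sc_cohort(cfg)
        norm = pp.normalize_log(adata)
        labels = pp.annotate_by_markers(
            norm,
            {
                "malignant": ["EPCAM_T", "KRT_T"],
                "T": ["CD3_T", "CD2_T"],
                "fibroblast": ["COL1_T", "COL3_T"],
            },
        )
        acc = (labels["label"] == adata.obs["cell_type"]).mean()
        assert acc >= 0.95
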