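"""Generators: marginal correctness, degenerate configs, reproducibility."""

import numpy as np
import pytest

from dualtaa import synthetic_data as sd
from dualtaa.calibration import roc_curve


def _uniform_rates(n_genes, pi, lam):
    n_types = len(sd.CELL_TYPES)
    return (
        np.full((n_genes, n_types), pi),
        np.full((n_genes, n_types), lam),
    )


class TestSCCohort:
    def test_zero_probability_gives_all_zero_matrix(self):
        pi, lam = _uniform_rates(30, 0.0, 2.0)
        cfg = sd.SCSimConfig(
            n_genes=30, n_patients=2, n_datasets=2, cells_per_patient=20,
            pi=pi, lam=lam, seed=0,
        )
        adata = sd.simulate_sc_cohort(cfg)
        assert adata.X.nnz == 0

    def test_dimensions_and_metadata_bookkeeping(self):
        cfg = sd.SCSimConfig(
            n_genes=50, n_patients=5, n_datasets=2, cells_per_patient=200, seed=0
        )
        adata = sd.simulate_sc_cohort(cfg)
        assert adata.shape == (1000, 50)
        assert set(adata.obs.columns) >= {"patient", "batch", "cell_type", "malignant"}
        assert adata.obs["patient"].nunique() == 5
        assert adata.obs["batch"].nunique() == 2
        assert not adata.obs.isna().any().any()

    def test_expression_probability_recovered_in_malignant_cells(self):
        # Monte-Carlo check: the empirical expressing fraction of a gene with
        # planted probability 0.6 stays within 3 binomial SEs at n = 10,000.
        pi, lam = _uniform_rates(10, 0.1, 2.0)
        pi[0, 0] = 0.6  # gene 0 in malignant cells
        cfg = sd.SCSimConfig(
            n_genes=10, n_patients=5, n_datasets=1, cells_per_patient=2000,
            cell_type_proportions={t: (1.0 if t == "malignant" else 0.0)
                                   for t in sd.CELL_TYPES},
            pi=pi, lam=lam, batch_effect_scale=0.0, seed=11,
        )
        adata = sd.simulate_sc_cohort(cfg)
        col = np.asarray((adata.X[:, 0] > 0).todense()).ravel()
        se = np.sqrt(0.6 * 0.4 / adata.n_obs)
        assert abs(col.mean() - 0.6) < 3 * se

    def test_identical_seed_bit_identical_output(self):
        cfg = sd.SCSimConfig(n_genes=40, n_patients=3, n_datasets=2,
                             cells_per_patient=50, seed=5)
        a = sd.simulate_sc_cohort(cfg)
        b = sd.simulate_sc_cohort(cfg)
        assert (a.X != b.X).nnz == 0
        assert a.obs.equals(b.obs)

    def test_invalid_probability_rejected(self):
        pi, lam = _uniform_rates(5, 1.5, 2.0)
        cfg = sd.SCSimConfig(n_genes=5, n_patients=2, n_datasets=1,
                             cells_per_patient=10, pi=pi, lam=lam)
        with pytest.raises(sd.SimConfigError):
            sd.simulate_sc_cohort(cfg)

    def test_negative_mean_rejected(self):
        pi, lam = _uniform_rates(5, 0.5, 2.0)
        lam[2, 3] = -1.0
        cfg = sd.SCSimConfig(n_genes=5, n_patients=2, n_datasets=1,
                             cells_per_patient=10, pi=pi, lam=lam)
        with pytest.raises(sd.SimConfigError):
            sd.simulate_sc_cohort(cfg)

    def test_mito_genes_named_by_prefix(self):
        cfg = sd.SCSimConfig(n_genes=100, n_patients=2, n_datasets=1,
                             cells_per_patient=10, mito_gene_fraction=0.05, seed=0)
        adata = sd.simulate_sc_cohort(cfg)
        assert sum(g.startswith("MT-") for g in adata.var_names) == 5

    def test_mtx_roundtrip(self, tmp_path):
        cfg = sd.SCSimConfig(n_genes=30, n_patients=2, n_datasets=2,
                             cells_per_patient=25, seed=3)
        adata = sd.simulate_sc_cohort(cfg)
        sd.write_sc_cohort(adata, tmp_path / "cohort")
        back = sd.read_sc_cohort(tmp_path / "cohort")
        assert (back.X != adata.X).nnz == 0
        assert list(back.var_names) == list(adata.var_names)
        assert back.obs["malignant"].tolist() == adata.obs["malignant"].tolist()


class TestPairedPanel:
    def test_huge_separation_gives_perfect_auc(self):
        cfg = sd.PairedSimConfig(n_samples=200, separation=50.0,
                                 h_score_noise=0.0, seed=0)
        panel = sd.simulate_paired_panel(cfg)
        labels = (panel[["pct_1plus", "pct_2plus", "pct_3plus"]].sum(axis=1) > 0)
        res = roc_curve(panel["log2_tpm1"], labels.astype(int))
        assert res.auc == 1.0

    def test_zero_separation_gives_chance_auc(self):
        cfg = sd.PairedSimConfig(n_samples=2000, separation=0.0,
                                 prevalence=0.5, seed=1)
        panel = sd.simulate_paired_panel(cfg)
        res = roc_curve(panel["log2_tpm1"], panel["true_positive"])
        n1 = int(panel["true_positive"].sum())
        n0 = len(panel) - n1
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))  # U-statistic null SE
        assert abs(res.auc - 0.5) < 3 * se

    def test_hscore_positive_iff_latent_state_without_noise(self):
        cfg = sd.PairedSimConfig(n_samples=300, h_score_noise=0.0, seed=2)
        panel = sd.simulate_paired_panel(cfg)
        hs_pos = (panel[["pct_1plus", "pct_2plus", "pct_3plus"]].sum(axis=1) > 0)
        assert (hs_pos == panel["true_positive"].astype(bool)).all()

    def test_noise_flips_some_calls(self):
        cfg = sd.PairedSimConfig(n_samples=500, h_score_noise=0.3, seed=2)
        panel = sd.simulate_paired_panel(cfg)
        hs_pos = (panel[["pct_1plus", "pct_2plus", "pct_3plus"]].sum(axis=1) > 0)
        mismatch = (hs_pos != panel["true_positive"].astype(bool)).mean()
        assert 0.2 < mismatch < 0.4

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(sd.SimConfigError):
            sd.simulate_paired_panel(sd.PairedSimConfig(prevalence=0.0))


class TestCohort:
    def test_dual_positive_fraction_recovered(self):
        # with the first gene always positive the dual fraction equals the
        # second gene's planted 0.9
        cfg = sd.CohortSimConfig(
            n_samples=1000,
            positivity_fractions={"EGFR": 1.0, "MUC1": 0.9},
            seed=4,
        )
        sim = sd.simulate_cohort(cfg)
        frac = sim.truth["dual_positive"].mean()
        se = np.sqrt(0.9 * 0.1 / 1000)
        assert abs(frac - 0.9) < 3 * se

    def test_full_censoring_means_no_events(self):
        cfg = sd.CohortSimConfig(n_samples=200, censoring_rate=1.0, seed=0)
        sim = sd.simulate_cohort(cfg)
        assert (sim.clinical["event"] == 0).all()

    def test_no_censoring_means_all_events(self):
        cfg = sd.CohortSimConfig(n_samples=200, censoring_rate=0.0, seed=0)
        sim = sd.simulate_cohort(cfg)
        assert (sim.clinical["event"] == 1).all()

    def test_censoring_rate_approximately_respected(self):
        cfg = sd.CohortSimConfig(n_samples=2000, censoring_rate=0.3,
                                 hazard_ratio=1.0, seed=9)
        sim = sd.simulate_cohort(cfg)
        cens = 1 - sim.clinical["event"].mean()
        se = np.sqrt(0.3 * 0.7 / 2000)
        assert abs(cens - 0.3) < 4 * se

    def test_stage_distribution_and_positive_times(self):
        cfg = sd.CohortSimConfig(n_samples=500, seed=2)
        sim = sd.simulate_cohort(cfg)
        assert set(sim.clinical["stage"]) <= {"I", "II", "III", "IV"}
        assert (sim.clinical["time"] > 0).all()

    def test_invalid_hazard_ratio_rejected(self):
        with pytest.raises(sd.SimConfigError):
            sd.simulate_cohort(sd.CohortSimConfig(hazard_ratio=0.0))
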