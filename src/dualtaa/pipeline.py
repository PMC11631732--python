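"""End-to-end runner: simulate -> preprocess -> screen -> co-expression ->
IHC -> calibrate -> coverage -> survival, as one reproducible report.

Every stage writes its intermediate to the output directory; the final
``report.json`` carries a config hash and is bit-identical across reruns
with the same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import coexpr as cx
from . import sc_preprocess as pp
from . import survival as sv
from . import synthetic_data as sd
from . import taa_screen as ts

__all__ = ["default_config", "config_hash", "report_digest", "run_pipeline"]

logger = logging.getLogger("dualtaa")

#: Demo rates for the planted target genes, (expression probability, NB mean)
#: per cell type. The anchor (EGFR) and its best partner (MUC1) are frequent
#: in malignant cells and rare in stroma; the alternative partners co-occur
#: with the anchor in stromal populations too, so the pair ranking has
#: structure to recover.
_PLANTED = {
    "EGFR": {
        "malignant": (0.70, 3.0), "epithelial": (0.30, 1.5),
        "fibroblast": (0.05, 0.5), "endothelial": (0.05, 0.5),
        "T": (0.02, 0.3), "NK": (0.02, 0.3), "myeloid": (0.03, 0.3),
        "B": (0.02, 0.3),
    },
    "MUC1": {
        "malignant": (0.65, 3.0), "epithelial": (0.20, 1.0),
        "fibroblast": (0.02, 0.3), "endothelial": (0.02, 0.3),
        "T": (0.01, 0.3), "NK": (0.01, 0.3), "myeloid": (0.02, 0.3),
        "B": (0.01, 0.3),
    },
    "MET": {
        "malignant": (0.40, 2.0), "epithelial": (0.25, 1.0),
        "fibroblast": (0.35, 1.5), "endothelial": (0.20, 1.0),
        "T": (0.05, 0.3), "NK": (0.05, 0.3), "myeloid": (0.10, 0.5),
        "B": (0.05, 0.3),
    },
    "ERBB3": {
        "malignant": (0.35, 2.0), "epithelial": (0.30, 1.5),
        "fibroblast": (0.10, 0.5), "endothelial": (0.25, 1.0),
        "T": (0.05, 0.3), "NK": (0.05, 0.3), "myeloid": (0.05, 0.3),
        "B": (0.15, 0.5),
    },
    "TACSTD2": {
        "malignant": (0.45, 2.0), "epithelial": (0.40, 2.0),
        "fibroblast": (0.15, 0.8), "endothelial": (0.10, 0.5),
        "T": (0.05, 0.3), "NK": (0.05, 0.3), "myeloid": (0.20, 0.8),
        "B": (0.05, 0.3),
    },
}

#: Marker sets for the stand-in annotator; gene names follow the simulated
#: naming scheme (these are attached as planted genes of the demo config).
_DEMO_MARKERS = {
    "malignant": ["EPCAM_T", "KRT_T"],
    "T": ["CD3_T"],
    "fibroblast": ["COL1_T"],
}

_DEMO_MARKER_RATES = {
    "EPCAM_T": {"malignant": (0.8, 4.0), "epithelial": (0.6, 3.0)},
    "KRT_T": {"malignant": (0.7, 3.0), "epithelial": (0.5, 2.0)},
    "CD3_T": {"T": (0.8, 4.0)},
    "COL1_T": {"fibroblast": (0.8, 4.0)},
}


def default_config() -> dict:
    """Demo configuration: every analysis default equals the published
    workflow's value (QC 3 genes / 200 UMI / 20% mito, 1e6 + log, 30 PCs,
    6:2:2 split, 10-fold CV, top-100 surfaceome intersection, raw-count > 0
    co-expression, 10% patient threshold, H-score tiers 100/200, >= 1%
    co-positivity, stage III/IV); simulation sizes and tree count are scaled
    for a desk-size demo."""
    return {
        "seed": 0,
        "sc": {
            "n_genes": 300,
            "n_patients": 6,
            "n_datasets": 2,
            "cells_per_patient": 200,
            "dispersion": 0.5,
            "mito_gene_fraction": 0.02,
            "batch_effect_scale": 0.15,
        },
        "qc": {"min_genes_detected": 3, "min_umi": 200, "max_mito_fraction": 0.20},
        "normalize": {"scale": 1e6},
        "hvg": {"k": 150},
        "pca": {"n_components": 30},
        "batch": {"ridge_lambda": 1.0},
        "screen": {"n_trees": 100, "top_k": 100, "cv_folds": 10},
        "coexpr": {
            "anchor": "EGFR",
            "partners": ["MUC1", "MET", "ERBB3", "TACSTD2"],
            "threshold": 0.10,
            "min_cells": 10,
        },
        "paired": {
            "n_samples": 200,
            "markers": {
                "EGFR": {"true_threshold": 2.23, "separation": 3.0},
                "MUC1": {"true_threshold": 1.5, "separation": 3.0},
            },
            "prevalence": 0.5,
            "h_score_noise": 0.0,
        },
        "cohort": {
            "n_samples": 600,
            "positivity_fractions": {"EGFR": 0.95, "MUC1": 0.90},
            "hazard_ratio": 2.0,
            "censoring_rate": 0.3,
        },
        "survival": {"rule": "threshold", "contrast": "dual_high_vs_rest"},
    }


def _canonical(config: dict) -> str:
    return json.dumps(config, sort_keys=True, default=str)


def config_hash(config: dict) -> str:
    return hashlib.sha256(_canonical(config).encode()).hexdigest()[:16]


def report_digest(report: dict) -> str:
    return hashlib.sha256(_canonical(report).encode()).hexdigest()


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: dict | None = None, outdir=None, seed: int | None = None) -> dict:
    """Execute every stage in order and return the machine-readable report.

    Any stage failure is re-raised annotated with the stage name. With
    ``outdir`` set, all intermediates plus ``report.json`` are written there.
    """
    cfg = default_config()
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if seed is not None:
        cfg["seed"] = seed
    base_seed = int(cfg["seed"])
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {"config_hash": config_hash(cfg), "seed": base_seed}
    stage = "simulate_sc"
    try:
        _stage(stage)
        planted = dict(_PLANTED) | _DEMO_MARKER_RATES
        sc_cfg = sd.SCSimConfig(seed=base_seed, planted=planted, **cfg["sc"])
        adata = sd.simulate_sc_cohort(sc_cfg)
        if out is not None:
            sd.write_sc_cohort(adata, out / "sc_cohort")
        report["simulate_sc"] = {"n_cells": adata.n_obs, "n_genes": adata.n_vars}

        stage = "qc"
        _stage(stage)
        thresholds = pp.QCThresholds(**cfg["qc"])
        adata, qc_report = pp.qc_filter(adata, thresholds)
        if out is not None:
            pd.DataFrame([qc_report.__dict__]).to_csv(out / "qc_report.csv", index=False)
        report["qc"] = {
            k: v for k, v in qc_report.__dict__.items() if k != "warnings"
        }

        stage = "normalize"
        _stage(stage)
        norm = pp.normalize_log(adata, scale=cfg["normalize"]["scale"])

        stage = "hvg"
        _stage(stage)
        hvg = pp.select_hvg(norm, k=min(cfg["hvg"]["k"], norm.n_vars))
        report["hvg"] = {"n_selected": len(hvg)}

        stage = "pca"
        _stage(stage)
        pca = pp.pca_embed(norm, genes=hvg, n_components=cfg["pca"]["n_components"])
        report["pca"] = {
            "n_components": int(pca.embedding.shape[1]),
            "explained_variance_ratio_sum": float(pca.explained_variance_ratio.sum()),
        }

        stage = "batch_correct"
        _stage(stage)
        corrected = pp.regress_batch(
            pca.embedding, norm.obs["batch"].to_numpy(), cfg["batch"]["ridge_lambda"]
        )
        if out is not None:
            np.savetxt(out / "embedding_corrected.tsv", corrected, delimiter="\t")

        stage = "screen"
        _stage(stage)
        feature_genes = sorted(set(hvg) | set(_PLANTED))
        feature_genes = [g for g in feature_genes if g in norm.var_names]
        labels = np.where(norm.obs["malignant"].to_numpy(), "tumor", "normal")
        ranking = ts.rank_features(
            norm[:, feature_genes],
            labels,
            n_trees=cfg["screen"]["n_trees"],
            cv_folds=cfg["screen"]["cv_folds"],
            seed=base_seed,
        )
        surfaceome = sorted(
            set(_PLANTED) | {g for i, g in enumerate(norm.var_names) if i % 3 == 0}
        )
        candidates = ts.intersect_surfaceome(
            ranking, surfaceome, top_k=cfg["screen"]["top_k"]
        )
        ranking["is_surface"] = ranking["gene"].isin(surfaceome)
        if out is not None:
            ranking.to_csv(out / "ranking.csv", index=False)
            (out / "candidates.txt").write_text("\n".join(candidates) + "\n")
        anchor = cfg["coexpr"]["anchor"]
        report["screen"] = {
            "test_auc": ranking.attrs["test_auc"],
            "validation_auc": ranking.attrs["validation_auc"],
            "n_candidates": len(candidates),
            "top10": candidates[:10],
            "anchor_rank": int(
                ranking.loc[ranking["gene"] == anchor, "rank"].iloc[0]
            )
            if anchor in set(ranking["gene"])
            else None,
        }

        stage = "coexpr"
        _stage(stage)
        tables, summary = cx.partner_screen(
            adata,
            anchor,
            cfg["coexpr"]["partners"],
            threshold=cfg["coexpr"]["threshold"],
            min_cells=cfg["coexpr"]["min_cells"],
        )
        best_partner = (
            summary.sort_values("specificity_rank")["partner"].iloc[0]
            if not summary.empty
            else None
        )
        test = cx.compare_malignant_vs_stromal(tables[best_partner])
        if out is not None:
            pd.concat(tables.values()).to_csv(out / "coexpression.csv", index=False)
            summary.to_csv(out / "coexpression_summary.csv", index=False)
        report["coexpr"] = {
            "summary": summary.to_dict(orient="records"),
            "best_partner": best_partner,
            "malignant_vs_stromal_p": test["p_value"],
        }

        stage = "calibrate"
        _stage(stage)
        calib = {}
        thresholds_by_marker = {}
        for i, (marker, mcfg) in enumerate(sorted(cfg["paired"]["markers"].items())):
            pcfg = sd.PairedSimConfig(
                n_samples=cfg["paired"]["n_samples"],
                prevalence=cfg["paired"]["prevalence"],
                h_score_noise=cfg["paired"]["h_score_noise"],
                marker=marker,
                seed=base_seed + 1000 * (i + 1),
                **mcfg,
            )
            panel = sd.simulate_paired_panel(pcfg)
            if out is not None:
                panel.to_csv(out / f"paired_{marker}.csv", index=False)
            result = cal.calibrate_marker(panel, marker)
            thresholds_by_marker[marker] = result.cutoff
            calib[marker] = {
                "auc": result.auc,
                "youden_j": result.youden_j,
                "cutoff": result.cutoff,
                "true_threshold": pcfg.true_threshold,
                "n_pos": result.n_pos,
                "n_neg": result.n_neg,
            }
        if out is not None:
            (out / "calibration.json").write_text(json.dumps(calib, indent=2))
        report["calibration"] = calib

        stage = "coverage"
        _stage(stage)
        ccfg = sd.CohortSimConfig(seed=base_seed + 5000, **cfg["cohort"])
        cohort = sd.simulate_cohort(ccfg)
        coverage = cal.apply_cutoffs(cohort.expression, thresholds_by_marker)
        if out is not None:
            cohort.expression.to_csv(out / "cohort_expression.tsv", sep="\t")
            cohort.clinical.to_csv(out / "cohort_clinical.csv", index=False)
            coverage.per_marker.to_csv(out / "coverage.csv", index=False)
        report["coverage"] = {
            "per_marker": coverage.per_marker.to_dict(orient="records"),
            "dual_pct": coverage.dual_pct,
            "dual_n": coverage.dual_n_pos,
            "n_total": coverage.n_total,
        }

        stage = "survival"
        _stage(stage)
        genes = list(cfg["cohort"]["positivity_fractions"])[:2]
        records = cohort.clinical.join(cohort.expression, on="sample_id")
        grouped = sv.group_by_dual_expression(
            records, genes[0], genes[1],
            rule=cfg["survival"]["rule"],
            thresholds=thresholds_by_marker
            if cfg["survival"]["rule"] == "threshold"
            else None,
        )
        if cfg["survival"]["contrast"] == "dual_high_vs_rest":
            in_a = grouped["group"] == "dual-high"
            a, b = grouped[in_a], grouped[~in_a]
        else:  # dual-high vs dual-low
            a = grouped[grouped["group"] == "dual-high"]
            b = grouped[grouped["group"] == "dual-low"]
        chi2, p = sv.logrank_test(a["time"], a["event"], b["time"], b["event"])
        grouped["dual_high"] = (grouped["group"] == "dual-high").astype(int)
        try:
            cox = sv.cox_univariate(grouped, "dual_high")
            cox_summary = {
                "hazard_ratio": cox.hazard_ratio,
                "ci": [cox.ci_lower, cox.ci_upper],
                "p": cox.p_value,
                "converged": cox.converged,
            }
        except ValueError:
            cox_summary = None
        if out is not None:
            grouped.to_csv(out / "survival_groups.csv", index=False)
        report["survival"] = {
            "rule": cfg["survival"]["rule"],
            "contrast": cfg["survival"]["contrast"],
            "n_dual_high": int((grouped["group"] == "dual-high").sum()),
            "n_other": int((grouped["group"] != "dual-high").sum()),
            "logrank_chi2": chi2,
            "logrank_p": p,
            "cox": cox_summary,
        }
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    report["digest"] = report_digest(
        {k: v for k, v in report.items() if k != "digest"}
    )
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
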