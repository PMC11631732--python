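"""Synthetic input generators with known ground truth.

Three generators stand in for the data modalities the pipeline consumes:

* :func:`simulate_sc_cohort` — a multi-patient, multi-batch single-cell UMI
  count matrix with malignant and stromal populations, drawn from a
  zero-inflated negative binomial model with per-(batch, gene) multiplicative
  batch effects.
* :func:`simulate_paired_panel` — paired IHC staining percentages and RNA
  scores (log2(TPM+1)) for one marker, with a known true RNA threshold
  separating IHC-positive from IHC-negative samples at a configurable margin.
* :func:`simulate_cohort` — a bulk expression cohort with known per-gene
  positivity fractions, tumor stages, and exponential survival times whose
  hazard is multiplied for dual-positive samples.

All generators are deterministic given ``config.seed``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CELL_TYPES",
    "STROMAL_TYPES",
    "SimConfigError",
    "SCSimConfig",
    "PairedSimConfig",
    "CohortSimConfig",
    "CohortSim",
    "simulate_sc_cohort",
    "simulate_paired_panel",
    "simulate_cohort",
    "default_rates",
    "write_sc_cohort",
    "read_sc_cohort",
]

#: Cell populations of the simulated tumor microenvironment, in the fixed
#: order used for rate matrices and tie-breaking.
CELL_TYPES: tuple[str, ...] = (
    "malignant",
    "epithelial",
    "fibroblast",
    "endothelial",
    "T",
    "NK",
    "myeloid",
    "B",
)

#: Everything that is not malignant counts as stroma for specificity views.
STROMAL_TYPES: tuple[str, ...] = tuple(t for t in CELL_TYPES if t != "malignant")

_DEFAULT_PROPORTIONS: dict[str, float] = {
    "malignant": 0.30,
    "epithelial": 0.15,
    "fibroblast": 0.10,
    "endothelial": 0.05,
    "T": 0.15,
    "NK": 0.05,
    "myeloid": 0.10,
    "B": 0.10,
}


class SimConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def _check_prob(name: str, value: np.ndarray | float) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise SimConfigError(f"{name} must lie in [0, 1]")


@dataclass
class SCSimConfig:
    """Configuration of the single-cell cohort generator.

    ``pi`` (expression probability) and ``lam`` (negative-binomial mean of
    expressed cells) are ``n_genes x len(CELL_TYPES)`` arrays; if omitted they
    are drawn once from :func:`default_rates` using the config seed.
    ``planted`` overrides rates for named genes, e.g.
    ``{"EGFR": {"malignant": (0.8, 4.0)}}`` plants an (expression probability,
    mean) pair for malignant cells.
    """

    n_genes: int = 1000
    n_patients: int = 8
    n_datasets: int = 2
    cells_per_patient: int = 300
    cell_type_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    pi: np.ndarray | None = None
    lam: np.ndarray | None = None
    planted: Mapping[str, Mapping[str, tuple[float, float]]] = field(default_factory=dict)
    gene_names: Sequence[str] | None = None
    dispersion: float = 0.5
    mito_gene_fraction: float = 0.02
    batch_effect_scale: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_patients, self.n_datasets, self.cells_per_patient) < 1:
            raise SimConfigError("counts must be positive")
        if self.n_datasets > self.n_patients:
            raise SimConfigError("need at least one patient per dataset")
        props = np.array([self.cell_type_proportions.get(t, 0.0) for t in CELL_TYPES])
        _check_prob("cell_type_proportions", props)
        if not math.isclose(props.sum(), 1.0, abs_tol=1e-8):
            raise SimConfigError("cell_type_proportions must sum to 1")
        if self.pi is not None:
            if np.asarray(self.pi).shape != (self.n_genes, len(CELL_TYPES)):
                raise SimConfigError("pi must be n_genes x n_cell_types")
            _check_prob("pi", np.asarray(self.pi))
        if self.lam is not None:
            if np.asarray(self.lam).shape != (self.n_genes, len(CELL_TYPES)):
                raise SimConfigError("lam must be n_genes x n_cell_types")
            if np.any(np.asarray(self.lam) <= 0):
                raise SimConfigError("lam must be > 0")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be >= 0")
        _check_prob("mito_gene_fraction", self.mito_gene_fraction)
        if self.batch_effect_scale < 0:
            raise SimConfigError("batch_effect_scale must be >= 0")


def default_rates(
    n_genes: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw baseline per-gene per-cell-type expression rates.

    Most genes share a low expression probability across cell types; a random
    tenth receive a boosted probability in one random type so that variable
    and type-discriminating genes exist for HVG selection and annotation.
    """
    n_types = len(CELL_TYPES)
    base_pi = np.clip(rng.beta(1.5, 4.0, size=n_genes), 0.02, 0.8)
    pi = np.tile(base_pi[:, None], (1, n_types))
    n_marked = max(1, n_genes // 10)
    marked = rng.choice(n_genes, size=n_marked, replace=False)
    boosted_type = rng.integers(0, n_types, size=n_marked)
    pi[marked, boosted_type] = np.clip(pi[marked, boosted_type] * 3.0, 0.0, 0.9)
    base_lam = np.clip(rng.lognormal(mean=1.2, sigma=0.5, size=n_genes), 0.3, None)
    lam = np.tile(base_lam[:, None], (1, n_types))
    lam[marked, boosted_type] *= 2.0
    return pi, lam


def _truncated_nb(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Zero-truncated NB draw (Var = m + dispersion * m^2; Poisson at 0).

    Sampling is conditional on count >= 1 via the inverse CDF, so that a gene
    expressed with probability pi has expressing-cell fraction exactly pi.
    """
    from scipy import stats as _st

    u = rng.random(mean.shape)
    if dispersion == 0:
        p0 = np.exp(-mean)
        return _st.poisson.ppf(p0 + (1 - p0) * u, mean).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    p0 = p**r
    return _st.nbinom.ppf(p0 + (1 - p0) * u, r, p).astype(np.int64)


def simulate_sc_cohort(config: SCSimConfig) -> ad.AnnData:
    """Generate a multi-batch single-cell UMI count matrix.

    Gene ``g`` in a cell of type ``t`` is expressed with probability
    ``pi[g, t]``; expressed entries are zero-truncated negative binomial with
    underlying mean ``lam[g, t]`` scaled by a log-normal per-(batch, gene)
    multiplier of scale ``batch_effect_scale``. Because expressed entries are
    truncated at >= 1, ``pi[g, t]`` is exactly the expected expressing-cell
    fraction of gene ``g`` in cell type ``t``. Returns an :class:`anndata.AnnData` with cells as
    observations, raw counts in ``X`` (CSR), and per-cell metadata columns
    ``patient``, ``batch``, ``cell_type``, ``malignant``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    pi, lam = config.pi, config.lam
    if pi is None or lam is None:
        d_pi, d_lam = default_rates(config.n_genes, rng)
        pi = d_pi if pi is None else np.asarray(pi, dtype=float)
        lam = d_lam if lam is None else np.asarray(lam, dtype=float)
    else:
        pi = np.asarray(pi, dtype=float)
        lam = np.asarray(lam, dtype=float)

    # Gene naming: mito genes first (MT- prefix), then planted names, then G#.
    n_mito = math.ceil(config.mito_gene_fraction * config.n_genes)
    if config.gene_names is not None:
        gene_names = list(config.gene_names)
        if len(gene_names) != config.n_genes:
            raise SimConfigError("gene_names length must equal n_genes")
    else:
        gene_names = [f"MT-G{i}" for i in range(n_mito)]
        planted_names = [g for g in config.planted if not g.startswith("MT-")]
        gene_names += planted_names
        i = 0
        while len(gene_names) < config.n_genes:
            name = f"G{i}"
            if name not in config.planted:
                gene_names.append(name)
            i += 1
        gene_names = gene_names[: config.n_genes]

    pi = pi.copy()
    lam = lam.copy()
    name_index = {g: i for i, g in enumerate(gene_names)}
    type_index = {t: j for j, t in enumerate(CELL_TYPES)}
    for gene, per_type in config.planted.items():
        if gene not in name_index:
            raise SimConfigError(f"planted gene {gene!r} not among gene names")
        for cell_type, (p, m) in per_type.items():
            _check_prob(f"planted pi for {gene}", p)
            if m <= 0:
                raise SimConfigError(f"planted mean for {gene} must be > 0")
            pi[name_index[gene], type_index[cell_type]] = p
            lam[name_index[gene], type_index[cell_type]] = m

    props = np.array([config.cell_type_proportions.get(t, 0.0) for t in CELL_TYPES])
    n_cells = config.n_patients * config.cells_per_patient
    patients = np.repeat(
        [f"P{i}" for i in range(config.n_patients)], config.cells_per_patient
    )
    # Patients assigned to datasets round-robin.
    patient_batch = {
        f"P{i}": f"D{i % config.n_datasets}" for i in range(config.n_patients)
    }
    batches = np.array([patient_batch[p] for p in patients])
    type_idx = rng.choice(len(CELL_TYPES), size=n_cells, p=props)

    batch_mult = {
        f"D{b}": rng.lognormal(0.0, config.batch_effect_scale, size=config.n_genes)
        if config.batch_effect_scale > 0
        else np.ones(config.n_genes)
        for b in range(config.n_datasets)
    }

    blocks = []
    order = []
    for b in sorted(set(batches)):
        for j in range(len(CELL_TYPES)):
            mask = (batches == b) & (type_idx == j)
            m = int(mask.sum())
            if m == 0:
                continue
            mean = lam[:, j] * batch_mult[b]  # (n_genes,)
            expressed = rng.random((m, config.n_genes)) < pi[:, j][None, :]
            counts = np.zeros((m, config.n_genes), dtype=np.int64)
            idx = np.nonzero(expressed)
            if idx[0].size:
                mean_mat = np.broadcast_to(mean, (m, config.n_genes))
                counts[idx] = _truncated_nb(rng, mean_mat[idx], config.dispersion)
            blocks.append(sp.csr_matrix(counts))
            order.append(np.nonzero(mask)[0])
    if blocks:
        perm = np.concatenate(order)
        X = sp.vstack(blocks).tocsr()
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        X = X[inv]
    else:  # pragma: no cover - n_cells >= 1 by validation
        X = sp.csr_matrix((0, config.n_genes), dtype=np.int64)

    obs = pd.DataFrame(
        {
            "patient": patients,
            "batch": batches,
            "cell_type": [CELL_TYPES[j] for j in type_idx],
            "malignant": [CELL_TYPES[j] == "malignant" for j in type_idx],
        },
        index=[f"cell{i}" for i in range(n_cells)],
    )
    var = pd.DataFrame(index=pd.Index(gene_names, name="gene"))
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["sim"] = {"seed": config.seed, "dispersion": config.dispersion}
    return adata


@dataclass
class PairedSimConfig:
    """Paired IHC + RNA panel generator settings.

    ``separation`` is the gap between positive and negative RNA score means in
    units of the score SD (``rna_sd``); the implied ROC AUC is
    ``Phi(separation / sqrt(2))``. ``h_score_noise`` is the probability that a
    sample's IHC call is flipped relative to its latent RNA state, producing
    imperfect IHC/RNA concordance.
    """

    n_samples: int = 100
    true_threshold: float = 1.5
    separation: float = 3.0
    prevalence: float = 0.5
    h_score_noise: float = 0.0
    rna_sd: float = 0.5
    marker: str = "EGFR"
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise SimConfigError("n_samples must be positive")
        if not 0 < self.prevalence < 1:
            raise SimConfigError("prevalence must be in (0, 1)")
        if self.separation < 0:
            raise SimConfigError("separation must be >= 0")
        _check_prob("h_score_noise", self.h_score_noise)
        if self.rna_sd <= 0:
            raise SimConfigError("rna_sd must be > 0")
        if self.true_threshold < 0:
            raise SimConfigError("true_threshold is in log2(TPM+1) units, >= 0")


def simulate_paired_panel(config: PairedSimConfig) -> pd.DataFrame:
    """Generate paired IHC staining percentages and RNA scores for one marker.

    Returns a DataFrame with columns ``sample_id``, ``marker``, ``pct_1plus``,
    ``pct_2plus``, ``pct_3plus``, ``log2_tpm1``, ``true_positive``. Latent
    positives receive RNA scores centred ``separation/2`` SDs above the true
    threshold, negatives symmetrically below; the IHC H-score is positive iff
    the (possibly noise-flipped) latent state is positive.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    state = rng.random(n) < config.prevalence
    offset = 0.5 * config.separation * config.rna_sd
    center = np.where(state, config.true_threshold + offset, config.true_threshold - offset)
    scores = np.clip(center + rng.normal(0.0, config.rna_sd, size=n), 0.0, None)

    ihc_state = state.copy()
    if config.h_score_noise > 0:
        flip = rng.random(n) < config.h_score_noise
        ihc_state = np.where(flip, ~ihc_state, ihc_state)

    pcts = np.zeros((n, 3))
    pos_idx = np.nonzero(ihc_state)[0]
    if pos_idx.size:
        total = rng.uniform(10.0, 100.0, size=pos_idx.size)
        weights = rng.dirichlet(np.ones(3), size=pos_idx.size)
        pcts[pos_idx] = total[:, None] * weights

    out = pd.DataFrame(
        {
            "sample_id": [f"PDX{i}" for i in range(n)],
            "marker": config.marker,
            "pct_1plus": pcts[:, 0],
            "pct_2plus": pcts[:, 1],
            "pct_3plus": pcts[:, 2],
            "log2_tpm1": scores,
            "true_positive": state.astype(int),
        }
    )
    out.attrs["true_threshold"] = config.true_threshold
    return out


@dataclass
class CohortSimConfig:
    """Bulk cohort generator with known positivity fractions and survival.

    Per-gene positivity states are independent Bernoulli draws at the
    configured fractions; positive samples express at ``mu_pos`` (log2(TPM+1)),
    negative at ``mu_neg``, well separated by default. Survival times are
    exponential with the baseline hazard multiplied by ``hazard_ratio`` for
    samples positive for the first two configured genes (the dual-target
    anchor pair). Censoring is independent exponential calibrated so that
    roughly ``censoring_rate`` of baseline-hazard samples are censored.
    """

    n_samples: int = 500
    positivity_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"EGFR": 0.95, "MUC1": 0.9}
    )
    mu_pos: float = 4.0
    mu_neg: float = 0.5
    sd_pos: float = 0.5
    sd_neg: float = 0.3
    stage_probs: Mapping[str, float] = field(
        default_factory=lambda: {"I": 0.30, "II": 0.15, "III": 0.35, "IV": 0.20}
    )
    baseline_hazard: float = 1.0 / 1000.0
    hazard_ratio: float = 2.0
    censoring_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise SimConfigError("n_samples must be positive")
        if len(self.positivity_fractions) < 1:
            raise SimConfigError("need at least one gene")
        for g, f in self.positivity_fractions.items():
            _check_prob(f"positivity fraction of {g}", f)
        probs = np.array(list(self.stage_probs.values()), dtype=float)
        _check_prob("stage_probs", probs)
        if not math.isclose(probs.sum(), 1.0, abs_tol=1e-8):
            raise SimConfigError("stage_probs must sum to 1")
        if self.baseline_hazard <= 0:
            raise SimConfigError("baseline_hazard must be > 0")
        if self.hazard_ratio <= 0:
            raise SimConfigError("hazard_ratio must be > 0")
        _check_prob("censoring_rate", self.censoring_rate)
        if self.mu_neg >= self.mu_pos:
            raise SimConfigError("mu_neg must be below mu_pos")


@dataclass
class CohortSim:
    """Expression (samples x genes, log2(TPM+1)), clinical and truth tables."""

    expression: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame


def simulate_cohort(config: CohortSimConfig) -> CohortSim:
    """Generate a bulk expression cohort with clinical annotations."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    genes = list(config.positivity_fractions)
    sample_ids = [f"S{i:04d}" for i in range(n)]

    states = {
        g: rng.random(n) < config.positivity_fractions[g] for g in genes
    }
    expr = {}
    for g in genes:
        pos = states[g]
        vals = np.where(
            pos,
            rng.normal(config.mu_pos, config.sd_pos, size=n),
            rng.normal(config.mu_neg, config.sd_neg, size=n),
        )
        expr[g] = np.clip(vals, 0.0, None)
    expression = pd.DataFrame(expr, index=sample_ids)

    stages = list(config.stage_probs)
    stage = rng.choice(stages, size=n, p=list(config.stage_probs.values()))

    dual = np.ones(n, dtype=bool)
    for g in genes[:2]:
        dual &= states[g]
    hazard = config.baseline_hazard * np.where(dual, config.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    r = config.censoring_rate
    if r == 0:
        time, event = event_time, np.ones(n, dtype=int)
    elif r == 1:
        time, event = event_time, np.zeros(n, dtype=int)
    else:
        cens_hazard = config.baseline_hazard * r / (1.0 - r)
        cens_time = rng.exponential(1.0 / cens_hazard, size=n)
        event = (event_time <= cens_time).astype(int)
        time = np.minimum(event_time, cens_time)
    time = np.maximum(time, 1e-9)  # times must be strictly positive

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "time": time,
            "event": event,
            "stage": stage,
        }
    )
    truth = pd.DataFrame(
        {f"pos_{g}": states[g].astype(int) for g in genes}
        | {"dual_positive": dual.astype(int)},
        index=sample_ids,
    )
    return CohortSim(expression=expression, clinical=clinical, truth=truth)


def write_sc_cohort(adata: ad.AnnData, outdir) -> None:
    """Write counts as MTX with genes.tsv / cells.tsv sidecars."""
    import os

    from scipy.io import mmwrite

    os.makedirs(outdir, exist_ok=True)
    mmwrite(os.path.join(outdir, "counts.mtx"), sp.coo_matrix(adata.X))
    adata.var.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t")
    adata.obs.to_csv(os.path.join(outdir, "cells.tsv"), sep="\t")


def read_sc_cohort(outdir) -> ad.AnnData:
    """Read a cohort written by :func:`write_sc_cohort`."""
    import os

    from scipy.io import mmread

    X = sp.csr_matrix(mmread(os.path.join(outdir, "counts.mtx")))
    var = pd.read_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index_col=0)
    obs = pd.read_csv(os.path.join(outdir, "cells.tsv"), sep="\t", index_col=0)
    if "malignant" in obs:
        obs["malignant"] = obs["malignant"].astype(bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ad.AnnData(X=X, obs=obs, var=var)
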