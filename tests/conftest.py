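import numpy as np
import pytest

from dualtaa import synthetic_data as sd


@pytest.fixture(scope="session")
def tumor_normal_adata():
    """Small two-batch cohort with planted anchor/partner structure.

    EGFR and MUC1 are frequent in malignant cells and rare in stroma; MET is
    expressed in fibroblasts as well, giving the specificity ranking
    something to distinguish.
    """
    planted = {
        "EGFR": {"malignant": (0.7, 3.0), "fibroblast": (0.05, 0.5), "T": (0.02, 0.3)},
        "MUC1": {"malignant": (0.6, 3.0), "fibroblast": (0.02, 0.3), "T": (0.01, 0.3)},
        "MET": {"malignant": (0.4, 2.0), "fibroblast": (0.4, 2.0), "T": (0.05, 0.3)},
    }
    cfg = sd.SCSimConfig(
        n_genes=120,
        n_patients=6,
        n_datasets=2,
        cells_per_patient=150,
        cell_type_proportions={
            "malignant": 0.4, "epithelial": 0.0, "fibroblast": 0.3,
            "endothelial": 0.0, "T": 0.3, "NK": 0.0, "myeloid": 0.0, "B": 0.0,
        },
        planted=planted,
        seed=7,
    )
    return sd.simulate_sc_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
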