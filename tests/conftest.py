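import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from scgxc.covariance import (
    context_covariance,
    relatedness_context_covariance,
)
from scgxc.preprocessing import CellDonorMap, ContextMatrix, standardize_contexts


def make_instance(seed, n_donors=8, cells_per_donor=6, k=3, kinship=None):
    """A small, fully random model instance for oracle comparisons."""
    rng = np.random.default_rng(seed)
    n = n_donors * cells_per_donor
    cell_map = CellDonorMap(np.repeat(np.arange(n_donors), cells_per_donor))
    C = standardize_contexts(ContextMatrix(rng.standard_normal((n, k))))
    dosage = rng.binomial(2, rng.uniform(0.1, 0.5), size=n_donors).astype(float)
    while np.allclose(dosage, dosage[0]):
        dosage = rng.binomial(2, 0.4, size=n_donors).astype(float)
    g = dosage[cell_map.assignment]
    X = np.column_stack([np.ones(n), g])
    y = rng.standard_normal(n)
    Sigma = context_covariance(C)
    RSigma = relatedness_context_covariance(cell_map, C, kinship=kinship)
    return {
        "rng": rng, "n": n, "cell_map": cell_map, "C": C, "dosage": dosage,
        "g": g, "X": X, "y": y, "Sigma": Sigma, "RSigma": RSigma,
    }


@pytest.fixture
def small_instance():
    return make_instance(seed=7)
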