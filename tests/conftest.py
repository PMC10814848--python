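import numpy as np
import pytest

from refstab.ct_data import CtMatrix, SampleMeta
from refstab.synth import default_study_config, generate


def make_matrix(ct, genes=None, donors=None, conditions=None, efficiency=None):
    """Small CtMatrix builder for tests.

    ``donors``/``conditions`` default to one donor and a distinct
    condition per sample, so any grid is a valid matrix.
    """
    ct = np.asarray(ct, dtype=float)
    n_genes, n_samples = ct.shape
    genes = genes or [f"G{i + 1}" for i in range(n_genes)]
    donors = donors or ["D1"] * n_samples
    conditions = conditions or [f"C{j + 1}" for j in range(n_samples)]
    samples = [
        SampleMeta(f"S{j + 1}", donors[j], conditions[j]) for j in range(n_samples)
    ]
    return CtMatrix(genes=genes, samples=samples, ct=ct, efficiency=efficiency or {})


@pytest.fixture
def worked_matrix():
    """3 genes x 4 samples worked example used against brute-force oracles."""
    return make_matrix(
        [[10, 10, 10, 10], [11, 12, 11, 12], [15, 14, 15, 16]],
        genes=["A", "B", "C"],
    )


@pytest.fixture
def study_matrix():
    """One draw of the default synthetic study design (8 genes x 12 samples)."""
    return generate(default_study_config(seed=7))


@pytest.fixture
def study_hkg_matrix(study_matrix):
    return study_matrix.subset(genes=["ACTB", "EF1A", "GAPDH", "RPLP0", "TBP"])
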