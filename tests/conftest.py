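import numpy as np
import pytest

from truncalis.io_model import PresenceMatrix


def make_matrix(presence, patient_id="P1", genes=None, af=None, ccf=None, biopsy_ids=None):
    presence = np.asarray(presence, dtype=bool)
    n_var, n_b = presence.shape
    biopsy_ids = biopsy_ids or [f"B{j + 1}" for j in range(n_b)]
    keys = [("chr1", i + 1, "A", "T") for i in range(n_var)]
    return PresenceMatrix(
        patient_id, biopsy_ids, keys, presence, af=af, ccf=ccf, genes=genes
    )


@pytest.fixture
def f1_matrix():
    """v1 in B1-B4, v2 in B1-B3, v3 in B1 only."""
    return make_matrix(
        [[1, 1, 1, 1], [1, 1, 1, 0], [1, 0, 0, 0]],
        genes=["EGFR", "TP53", "TTN"],
    )


def random_matrix(rng, max_biopsies=6, max_variants=50, patient_id="R"):
    """Random presence matrix with no all-absent rows and >=2 columns."""
    b = int(rng.integers(2, max_biopsies + 1))
    n = int(rng.integers(1, max_variants + 1))
    presence = rng.random((n, b)) < rng.uniform(0.2, 0.8)
    for i in range(n):
        if not presence[i].any():
            presence[i, rng.integers(0, b)] = True
    return make_matrix(presence, patient_id=patient_id)
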