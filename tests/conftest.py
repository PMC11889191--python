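import numpy as np
import pytest
from scipy.spatial.distance import cdist

from tmespat.config import SimConfig
from tmespat.synthetic import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across tests."""
    cfg = SimConfig(n_patients=3, cores_per_patient=2, seed=7)
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231209)


def brute_force_counts(ref, tgt, radius):
    """O(n^2) pair-count oracle: inclusive boundary, self-pairs excluded."""
    ref = np.asarray(ref, float).reshape(-1, 2)
    tgt = np.asarray(tgt, float).reshape(-1, 2)
    i_rt = 0
    if len(ref) and len(tgt):
        i_rt = int((cdist(ref, tgt) <= radius).sum())
    i_rr = 0
    if len(ref) >= 2:
        d = cdist(ref, ref)
        i_rr = int((d[np.triu_indices(len(ref), k=1)] <= radius).sum())
    return i_rt, i_rr
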