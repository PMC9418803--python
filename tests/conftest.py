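import numpy as np
import pytest

from fmtstrains.profiles import NucleotideProfile
from fmtstrains.synthetic import CohortConfig, generate_catalog, \
    generate_fmt_cohort


def make_profile(columns, sample_id="s", species_id="sp", L=None,
                 marker_bounds=None):
    """Profile from a dense list of per-position (A,C,G,T) count tuples."""
    counts = np.asarray(columns, dtype=np.int64).T
    L = L or counts.shape[1]
    full = np.zeros((4, L), dtype=np.int64)
    full[:, :counts.shape[1]] = counts
    mask = full.sum(axis=0) > 0
    return NucleotideProfile(sample_id, species_id, full, mask,
                             marker_bounds=marker_bounds or [(0, L)])


@pytest.fixture(scope="session")
def catalog20():
    return generate_catalog(20, feature_missing_rate=0.1, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A small rendered cohort shared across attribution/pipeline tests."""
    cfg = CohortConfig(n_cases=6, n_donors=3, n_species=40,
                       posts_per_case=(1, 2))
    return generate_fmt_cohort(cfg, seed=42)
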