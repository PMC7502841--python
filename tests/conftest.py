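import numpy as np
import pytest

from connectoprint import default_spec, generate_cohort, make_parcellation


@pytest.fixture(scope="session")
def small_parcellation():
    """30 nodes over the 13 networks (Gordon-proportioned blocks)."""
    return make_parcellation(30)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort shared by read-only tests."""
    return generate_cohort(default_spec(n_subjects=12, n_nodes=30, seed=42,
                                        structure_seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
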