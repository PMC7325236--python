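import numpy as np
import pytest

from methylbench import CohortConfig, MethylMatrix, Scale, generate_cohort


def make_matrix(values, scale=Scale.BETA):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return MethylMatrix(
        values,
        sample_ids=[f"S{i}" for i in range(n)],
        cpg_ids=[f"cg{j}" for j in range(p)],
        scale=scale,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Fully observed default healthy cohort (50 x 1000) plus its profile."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def desk_cohort():
    """Desk-scale healthy cohort (50 x 5000)."""
    return generate_cohort(CohortConfig(n_cpgs=5000, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
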