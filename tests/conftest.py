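import pytest

from lcpa.preprocess import prepare_indicators
from lcpa.simulate import default_cohort_config, generate_cohort


@pytest.fixture(scope="session")
def gen_config():
    return default_cohort_config()


@pytest.fixture(scope="session")
def cohort_500(gen_config):
    """One medium synthetic cohort shared across read-only tests."""
    table, truth = generate_cohort(gen_config, n=500, seed=3)
    return table, truth


@pytest.fixture(scope="session")
def processed_500(cohort_500):
    table, truth = cohort_500
    Y, specs = prepare_indicators(table)
    return Y, specs, truth


@pytest.fixture(scope="session")
def fitted_500(processed_500):
    """A 4-class fit on the shared cohort (kmeans + 2 random starts)."""
    from lcpa.lpa import fit_em

    Y, specs, truth = processed_500
    return fit_em(Y, specs, 4, n_restarts=3, seed=3, max_iter=300)
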