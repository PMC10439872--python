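import numpy as np
import pytest

from pacsim import default_config, generate_cohort, simulate_outcomes


@pytest.fixture(scope="session")
def gen_config():
    return default_config()


@pytest.fixture(scope="session")
def baseline_cohort(gen_config):
    """Small untreated cohort shared across read-only tests."""
    return generate_cohort(gen_config, 20, seed=7)


def make_treated(gen_config, n, arm, seed):
    cohort = generate_cohort(gen_config, n, seed)
    treated, truth = simulate_outcomes(cohort, gen_config, arm, seed + 100_000)
    return treated, truth


@pytest.fixture(scope="session")
def treated_le(gen_config):
    return make_treated(gen_config, 30, "LE", 42)


@pytest.fixture(scope="session")
def treated_lpi(gen_config):
    return make_treated(gen_config, 30, "LPI", 43)
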