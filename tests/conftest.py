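import pytest

from neoscreen.synth_cohort import (
    SimulationConfig,
    default_disease_groups,
    default_panel,
    simulate_cohort,
)


def make_config(n=2000, seed=7, groups=("PAHD", "PCD", "NICCD"), **kwargs):
    return SimulationConfig(
        n_newborns=n,
        seed=seed,
        analytes=default_panel(),
        disease_groups=default_disease_groups(groups),
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_config():
    return make_config()


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)
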