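import pytest
from hypothesis import HealthCheck, settings

from neofit.config import RunConfig, SimConfig
from neofit.simulate import generate_cohort

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def tiny_sim_config() -> SimConfig:
    """A few small samples: enough structure to exercise every stage, fast."""
    return SimConfig(
        n_samples_group_a=2,
        n_samples_group_b=2,
        mutation_burden_range=(40, 80),
        n_proteins=10,
        protein_length_range=(60, 120),
        n_epitopes=8,
        epitope_source_proteins=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_sim_config):
    return generate_cohort(tiny_sim_config)
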