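import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def quartet():
    """The four fully discordant patients: (grades, ai, adjudications) frames."""
    from drconcord.datasets import load_discordant_quartet

    return load_discordant_quartet()


@pytest.fixture(scope="session")
def study_tables():
    from drconcord.datasets import load_study_tables

    return load_study_tables()


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared by IO/pipeline tests."""
    from drconcord.simulate import default_config, simulate_dataset

    return simulate_dataset(default_config(n_patients=150, seed=42))
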