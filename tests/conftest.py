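import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study at the documented seed."""
    from ivtseq.simulate import simulate_study

    return simulate_study(seed=0)


@pytest.fixture(scope="session")
def default_config():
    from ivtseq.config import PipelineConfig

    return PipelineConfig()
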