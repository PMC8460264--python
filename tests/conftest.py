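import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fx():
    """Synthetic reference fixtures shared across the suite."""
    from riboevo import fixtures

    return fixtures()


@pytest.fixture(scope="session")
def models():
    from riboevo import load_models

    return load_models()
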