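import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def profile():
    from no2risk.risk_matrix import default_profile

    return default_profile()


@pytest.fixture(scope="session")
def default_campaign():
    """One synthetic campaign from the built-in study design (seed 1)."""
    from no2risk.synthetic_data import default_study_design, generate_campaign

    return generate_campaign(default_study_design(seed=1))


@pytest.fixture(scope="session")
def pooled_fixtures():
    from no2risk.synthetic_data import all_risk_fixtures

    return all_risk_fixtures()
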