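import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def signal_cohort():
    """n=272 cohort whose outcome is driven only by LDH, WBC, NIHSS, IL-6."""
    import strokerecur as sr
    from strokerecur.cohort import continuous_columns

    spec = sr.default_spec(272)
    df = sr.generate_covariates(spec, seed=7)
    return sr.assign_outcome(
        df, sr.biomarker_signal_model(), seed=7, continuous=continuous_columns(spec)
    )


@pytest.fixture(scope="session")
def joint_df():
    """Joint binary-exposure cohort with a known super-additive effect."""
    import strokerecur as sr

    return sr.simulate_joint_exposure(3000, or10=2.0, or01=1.5, or11=3.5, seed=42)
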