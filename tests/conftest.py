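import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_peptides():
    from aquamrm import masscalc

    return {p.display_name: p for p in masscalc.study_peptides()}


@pytest.fixture(scope="session")
def default_design():
    from aquamrm import synthetic_data

    return synthetic_data.AssayDesign()


@pytest.fixture()
def noiseless_calibration(default_design):
    """Noiseless calibration peaks + manifest (fast path)."""
    from aquamrm import synthetic_data as sd

    return sd.simulate_calibration_series(
        default_design, 1000.0, sd.NoiseModel.noiseless(seed=0)
    )


@pytest.fixture()
def noisy_calibration(default_design):
    """Calibration ladder with the assay's default 5% area CV, fixed seed."""
    from aquamrm import synthetic_data as sd

    return sd.simulate_calibration_series(
        default_design, 1000.0, sd.NoiseModel(seed=42, area_cv=0.05)
    )
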