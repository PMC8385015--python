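import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pkchip import datasets, imaging

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sn38_series():
    return datasets.load_invivo_series("SN38")


@pytest.fixture(scope="session")
def azd_series():
    return datasets.load_invivo_series("AZD0156")


@pytest.fixture(scope="session")
def synthetic_image():
    """Default synthetic spheroid shared by the imaging tests."""
    return imaging.generate_synthetic_spheroid(
        radius_um=150.0,
        pixel_size=1.0,
        n_cells=300,
        positive_fractions={"Ki67": 0.3, "gammaH2AX": 0.2, "CC3": 0.1},
        noise_sd=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def exponential_series():
    t = np.linspace(0.0, 24.0, 2401)
    from pkchip.pk import ConcentrationSeries

    return ConcentrationSeries("exp", t, 100.0 * np.exp(-0.2 * t), "simulated")
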