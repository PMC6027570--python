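import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from myoasl.synth import PhantomSlice, scenario_config, simulate_series

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def small_config(**overrides):
    """Baseline scenario on a 64x64 grid: fast, same physics."""
    base = dict(grid_shape=(64, 64), lv_center=(32.0, 32.0))
    base.update(overrides)
    return scenario_config("baseline", **base)


@pytest.fixture(scope="session")
def noise_free_phantom():
    return PhantomSlice(
        grid_shape=(64, 64),
        lv_center=(32.0, 32.0),
        endo_radius_mm=12.0,
        epi_radius_mm=20.0,
        pixel_spacing=1.5625,
        rv_insertion_angle=120.0,
        f_true=np.array([1.2, 0.3, 0.9, 1.5, 0.7, 2.1]),
        base_signal=100.0,
        snr=np.inf,
        flow_fluctuation_sd=0.0,
        heart_rate=93.0,
    )


@pytest.fixture(scope="session")
def noise_free_series(noise_free_phantom):
    return simulate_series(noise_free_phantom, seed=0)


@pytest.fixture(scope="session")
def noisy_series():
    phantom = PhantomSlice(
        grid_shape=(64, 64),
        lv_center=(32.0, 32.0),
        endo_radius_mm=12.0,
        epi_radius_mm=20.0,
        pixel_spacing=1.5625,
        rv_insertion_angle=120.0,
        f_true=np.full(6, 1.08),
        base_signal=100.0,
        snr=98.0,
        flow_fluctuation_sd=0.11,
        heart_rate=93.0,
    )
    return simulate_series(phantom, seed=11)
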