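import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eegstress as es

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_cohort():
    """The packaged 33-participant table."""
    return es.load_reference_cohort()


@pytest.fixture(scope="session")
def quiet_config():
    """Deterministic degenerate generator: oscillations only, no noise."""
    return es.GeneratorConfig(
        duration=180.0,
        background_scale=0.0,
        dc_offset_range=(0.0, 0.0),
        seed=0,
    )


@pytest.fixture(scope="session")
def default_recording():
    """One full-length synthetic recording with realistic structure."""
    return es.generate_recording(es.GeneratorConfig(seed=11), "control", 11)


def sinusoid_config(amplitude: float = 1.0, band: str = "alpha",
                    duration: float = 180.0) -> es.GeneratorConfig:
    """Generator planting a single pure sinusoid in one band, nothing else."""
    amps = {
        group: {ch: {band: amplitude} for ch in es.CHANNELS}
        for group in ("control", "stress", "neutral")
    }
    return es.GeneratorConfig(
        duration=duration,
        oscillation_mode="sinusoid",
        background_scale=0.0,
        dc_offset_range=(0.0, 0.0),
        band_amplitudes=amps,
        alpha_lateralization_effect=0.0,
    )


@pytest.fixture(scope="session")
def separable_problem():
    """1-D feature with control < 0 < stress: trivially separable."""
    rng = np.random.default_rng(42)
    x = np.r_[-1.0 - rng.random(10), 1.0 + rng.random(10)]
    y = np.r_[np.zeros(10, dtype=int), np.ones(10, dtype=int)]
    return x[:, None], y
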