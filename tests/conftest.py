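import numpy as np
import pytest

from brainthermo import GeneratorConfig, PatientSeriesParams


def circ_diff_hours(a: float, b: float) -> float:
    """Shortest circular distance between two clock times, hours."""
    d = abs(a - b) % 24.0
    return min(d, 24.0 - d)


@pytest.fixture
def default_config():
    return GeneratorConfig(seed=42)


@pytest.fixture
def white_noise_config():
    """Pure iid noise: AR coefficient, sensor noise and drift switched off."""
    return GeneratorConfig(
        seed=42,
        patient=PatientSeriesParams(
            ar1_coef=0.0, noise_sd=0.2, measurement_sd=0.0, drift_per_day=0.0
        ),
    )


@pytest.fixture
def clean_sinusoid():
    """Noiseless 48 h hourly sinusoid: 38 + 0.5 cos(2pi (t-18)/24)."""
    from brainthermo import TemperatureSeries

    t = np.arange(0.0, 48.0 + 1e-9, 1.0)
    y = 38.0 + 0.5 * np.cos(2 * np.pi * (t - 18.0) / 24.0)
    return TemperatureSeries(times=t, values=y, clock_anchor=0.0, preprocessed=True)
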