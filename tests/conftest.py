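import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from assrnet import ModelParameters, run_input_sweep

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params():
    return ModelParameters()


@pytest.fixture(scope="session")
def ipsc_sweeps(default_params):
    """Full-scale IPSC input-strength sweeps (40 Hz drive) for 5 base seeds.

    The central, most expensive simulation of the suite; shared by the
    beta-window, regime-snapshot and mechanism-correlation tests.
    """
    return {
        seed: run_input_sweep("IPSC", 40.0, params=default_params, base_seed=seed)
        for seed in (1, 2, 3, 4, 5)
    }


@pytest.fixture(scope="session")
def band_median():
    """Median PSD over the 2-100 Hz analysis band."""

    def _median(spec):
        band = (spec.freqs >= 2.0) & (spec.freqs <= 100.0)
        return float(np.median(spec.psd[band]))

    return _median
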