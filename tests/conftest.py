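import numpy as np
import pytest
from hypothesis import settings

from carscope.fcs_correlate import AutocorrelationCurve, multitau_lags
from carscope.fcs_model import FCSModelParams, model_G

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def model_lag_grid():
    """A realistic multi-tau lag grid: 1 us binning, lags up to 0.1 s."""
    return multitau_lags(1e-6, 0.1)


def curve_from_params(lags, params: FCSModelParams, sem=None) -> AutocorrelationCurve:
    """Noiseless model-generated curve (shared helper for roundtrip tests)."""
    return AutocorrelationCurve(lags, model_G(lags, params), sem=sem)


@pytest.fixture
def make_model_curve():
    return curve_from_params
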