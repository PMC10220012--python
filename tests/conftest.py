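import numpy as np
import pandas as pd
import pytest

from limnoflux.agemodel import AgeDepthEnsemble, AgeModelSettings
from limnoflux.calibration import CalibrationCurve

#: fast sampler settings shared by tests that only need a usable posterior
FAST_SETTINGS = dict(n_iter=2500, burn_in=700, n_members=150)


@pytest.fixture
def identity_curve():
    return CalibrationCurve.identity(-100, 10000)


@pytest.fixture
def linear_ensemble():
    """Single-member ensemble: exactly 10 yr/cm, collection year 2015."""
    depths = np.arange(0.0, 101.0, 5.0)
    return AgeDepthEnsemble(depths, (10.0 * depths)[None, :], 2015.0)


@pytest.fixture
def small_proxies():
    return pd.DataFrame(
        {
            "depth": [10.0, 20.0, 30.0, 40.0],
            "toc": [2.0, 2.0, 2.0, 2.0],
            "tic": [1.0, 1.0, 1.0, 1.0],
            "density": [0.5, 0.5, 0.5, 0.5],
        }
    )


@pytest.fixture
def fast_settings():
    return AgeModelSettings(**FAST_SETTINGS)
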