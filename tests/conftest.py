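import numpy as np
import pytest

from mabdev import synthetic as syn


@pytest.fixture
def dilute_concs():
    """Dilute-regime concentration grid used for intrinsic-viscosity work [mg/mL]."""
    return np.array([5.0, 10.0, 20.0, 30.0, 40.0, 50.0])


@pytest.fixture
def dls_concs():
    """DLS test concentration range [mg/mL]."""
    return np.array([1.0, 2.0, 5.0, 10.0, 15.0, 20.0])


@pytest.fixture
def igg_pair():
    """Table-style generating truths for the two subclasses under study."""
    return {
        "IgG1": {"eta_intrinsic": 8.28, "k_huggins": 5.30,
                 "ka": 3.84e5, "kd": 10.27e-4},
        "IgG3": {"eta_intrinsic": 10.42, "k_huggins": 1.27,
                 "ka": 2.41e5, "kd": 9.17e-4},
    }


@pytest.fixture
def gaussian_noise():
    def _make(sigma, seed=42):
        return syn.NoiseSpec("gaussian", sigma, seed)
    return _make
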