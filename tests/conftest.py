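import numpy as np
import pytest

from quincarb import synthetic
from quincarb.kinetics import AssaySeriesDesign, SchemeParams


@pytest.fixture
def scheme():
    return SchemeParams(k_max=0.12, K_a=4e-5)


@pytest.fixture
def design():
    return synthetic.DEFAULT_DESIGN


@pytest.fixture
def small_design():
    return AssaySeriesDesign(
        inhibitor_concentrations=(1e-5, 2.5e-5, 5e-5, 1e-4, 2e-4),
        incubation_times=(0.0, 2.0, 5.0, 10.0, 15.0, 20.0),
    )


@pytest.fixture
def fingerprints():
    return synthetic.generate_fingerprints(
        truth=synthetic.FingerprintTruth(seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
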