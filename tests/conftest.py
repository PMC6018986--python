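import numpy as np
import pytest

import orgdriver as od


@pytest.fixture(scope="session")
def design():
    return od.SampleDesign(seed=0)


@pytest.fixture(scope="session")
def noiseless_study():
    return od.simulate_expression(
        od.SampleDesign(seed=1), n_features=300, noise_cv=0.0, missing_rate=0.0,
        gain_unfractionated=1.0, gain_fractionated=1.0,
    )


@pytest.fixture(scope="session")
def noisy_study():
    return od.simulate_expression(od.SampleDesign(seed=2), n_features=1500)


@pytest.fixture(scope="session")
def landscape():
    return od.simulate_regulatory_landscape(od.SampleDesign(seed=3), seed=3, n_peaks=800, n_motifs=12, n_tads=80)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
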