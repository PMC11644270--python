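import numpy as np
import pytest

import dnrflux as d


@pytest.fixture(scope="session")
def short_drivers():
    """40 summer days of half-hourly drivers at 45°N (shared, read-only)."""
    return d.generate_drivers(40, 45.0, seed=101, start="2014-06-10")


@pytest.fixture(scope="session")
def noisefree_series(short_drivers):
    """Noise-free NEE over the short driver span, constant truth."""
    truth = d.constant_truth(40, start="2014-06-10", noise_sd=0.0, missing_fraction=0.0, seed=101)
    return d.generate_nee(short_drivers, truth), truth


@pytest.fixture(scope="session")
def noisy_series(short_drivers):
    """Noisy NEE (1 µmol m⁻² s⁻¹) with 10% gap-filled flags."""
    truth = d.constant_truth(40, start="2014-06-10", noise_sd=1.0, missing_fraction=0.1, seed=101)
    return d.qc_filter(d.generate_nee(short_drivers, truth), 0), truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
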