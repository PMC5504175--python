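import numpy as np
import pytest

from nuscs import PeakList, restrict, synth_fid, uniform_schedule


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def two_peak_model():
    """Two well-separated on-grid non-decaying peaks (strictly 2-sparse spectrum)."""
    return PeakList([(30, 1.0, 0.0, 0.0), (100, 0.6, 0.4, 0.0)])


@pytest.fixture
def lorentzian_model():
    """Two decaying peaks — an approximately sparse spectrum."""
    return PeakList([(30.0, 1.0, 0.0, 0.03), (100.0, 0.5, 0.0, 0.02)])


def make_nus(model, n, m, seed, noise_sigma=0.0):
    fid = synth_fid(model, n, noise_sigma=noise_sigma, seed=seed + 1)
    sched = uniform_schedule(n, m, seed)
    return fid, restrict(fid, sched)
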