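import numpy as np
import pytest

from clutchorder import anisotropy as an
from clutchorder import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noisy_scene():
    """One rendered FA scene with shot noise and its ground truth."""
    truth = sd.SceneTruth(n_fas=200, a_true=0.2, p_true=0.0, c_true=0.1,
                          g_true=1.1, seed=7, noise=True)
    ipa, ipe, pax, filled = sd.generate_fa_scene(truth)
    return ipa, ipe, pax, filled


@pytest.fixture(scope="session")
def noiseless_records():
    """Filtered FA records from a noiseless scene (A=0.2, p=20, C=0.1)."""
    truth = sd.SceneTruth(n_fas=200, a_true=0.2, p_true=20.0, c_true=0.1,
                          g_true=1.0, seed=5, noise=False)
    ipa, ipe, pax, _ = sd.generate_fa_scene(truth)
    r_map = an.anisotropy_map(an.PolarizedImagePair(ipa, ipe, 0.1), 1.0)
    labels = an.segment_fas(pax)
    return an.filter_fas(an.fa_properties(labels, r_map, 0.1))
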