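import numpy as np
import pytest

from irmspread import (analyze_platelet, scenario_preset, simulate_movie)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def collagen_run():
    """One collagen-like movie plus its full analysis (shared, read-only)."""
    seq, gt, roi, bg, ann = simulate_movie(scenario_preset("collagen_like", seed=3))
    res = analyze_platelet(seq, roi, bg)
    return seq, gt, roi, bg, ann, res


@pytest.fixture(scope="session")
def gaussian_noise_sequence():
    """Pure-noise movie: the no-platelet control."""
    from irmspread import IRMSequence
    rng = np.random.default_rng(7)
    frames = rng.normal(100.0, 2.0, size=(200, 64, 64))
    return IRMSequence(frames, frame_interval=1.0)
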