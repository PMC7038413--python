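import numpy as np
import pytest

from afdetect import SyntheticConfig, gen_database


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_db():
    """A small labeled synthetic database shared by pipeline-level tests."""
    return gen_database(8, SyntheticConfig(n_beats=800), seed=7)


def random_rr_windows(n_windows, n=21, seed=0):
    """Random positive RR windows mixing smooth and erratic regimes."""
    rng = np.random.default_rng(seed)
    wins = []
    for _ in range(n_windows):
        if rng.random() < 0.5:
            base = rng.uniform(500, 1100)
            w = base + rng.normal(0, rng.uniform(1, 30), n)
        else:
            w = rng.uniform(300, 1400, n)
        wins.append(np.clip(w, 260, None))
    return wins
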