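import numpy as np
import pandas as pd
import pytest


def fixation_frame(xy, trial=1, duration=0.2, participant=None):
    """Build a minimal valid fixation table from (x, y) pairs."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    df = pd.DataFrame({
        "trial": trial,
        "rank": np.arange(1, n + 1),
        "onset": np.arange(n) * (duration + 0.03),
        "duration": duration,
        "x": xy[:, 0],
        "y": xy[:, 1],
    })
    if participant is not None:
        df.insert(0, "participant", participant)
    return df


def random_scanpaths(rng, n_paths, max_len=30, spread=(4.0, 15.0)):
    """Random scanpaths mixing dense (revisit-rich) and sparse geometries."""
    for _ in range(n_paths):
        n = int(rng.integers(1, max_len + 1))
        half = float(rng.choice(spread))
        yield rng.uniform(-half, half, size=(n, 2))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
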