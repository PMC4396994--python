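import numpy as np
import pytest

from gminscan.hapstats import MISSING, HaplotypeWindow


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_window(rng, n1, n2, n_sites, missing_rate=0.0):
    """A random biallelic window, optionally with missing states."""
    seqs = rng.integers(0, 2, size=(n1 + n2, n_sites)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(seqs.shape) < missing_rate
        seqs[mask] = MISSING
    labels = np.array([1] * n1 + [2] * n2)
    return HaplotypeWindow(seqs, labels, window_id="rand")
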