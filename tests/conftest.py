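import numpy as np
import pytest

from msbgwo.data import Dataset, SyntheticSpec, generate_synthetic


class ScriptedRNG:
    """Stand-in generator returning pre-recorded uniform draws in order."""

    def __init__(self, arrays):
        self._queue = [np.asarray(a, dtype=float) for a in arrays]

    def random(self, n=None):
        if not self._queue:
            raise AssertionError("ScriptedRNG exhausted: unexpected extra draw")
        arr = self._queue.pop(0)
        if n is not None and arr.size != n:
            raise AssertionError(f"expected draw of size {n}, scripted {arr.size}")
        return arr


@pytest.fixture
def scripted_rng():
    return ScriptedRNG


@pytest.fixture(scope="session")
def separable_dataset():
    """Two point clouds perfectly separated on every feature."""
    n_per, d = 20, 4
    x = np.vstack([np.zeros((n_per, d)), np.ones((n_per, d))])
    y = np.concatenate([np.zeros(n_per, dtype=np.int8), np.ones(n_per, dtype=np.int8)])
    return Dataset(
        X=x, y=y, feature_names=[f"f{i}" for i in range(d)],
        normalized=True, positive_label="1",
    )


@pytest.fixture(scope="session")
def synthetic_default():
    """The default planted-feature study dataset plus ground truth."""
    ds, planted = generate_synthetic(SyntheticSpec())
    return ds, planted
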