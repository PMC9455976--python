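import warnings

import numpy as np
import pytest

from honeyprint import TaskConfig, run_task


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def _separable_two_class(rng, n=40, p=10, shift=6.0):
    """Two well-separated Gaussian classes in the first coordinate."""
    X = rng.standard_normal((n, p))
    labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    perm = rng.permutation(n)
    X, labels = X[perm], labels[perm]
    X[labels == "a", 0] += shift
    return X, labels


@pytest.fixture
def separable(rng):
    return _separable_two_class(rng)


@pytest.fixture(scope="session")
def task_results():
    """Full pipeline runs of the three frozen study presets (shared)."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for task in ("harvest_year", "botanical", "geographic"):
            out[task] = run_task(TaskConfig(task=task))
    return out
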