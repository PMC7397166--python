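import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ito.dataset_io import ExpressionDataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_dataset(matrix, labels, prefix="s"):
    """Small helper: wrap a raw array into an ExpressionDataset with generated ids."""
    matrix = np.asarray(matrix, dtype=float)
    n, f = matrix.shape
    return ExpressionDataset(
        matrix,
        np.asarray(labels, dtype=int),
        [f"{prefix}{i}" for i in range(n)],
        [f"f{j}" for j in range(f)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_dataset(rng):
    """30 samples x 8 continuous features, balanced-ish binary labels."""
    X = rng.standard_normal((30, 8))
    y = rng.integers(0, 2, size=30)
    y[:2] = [0, 1]  # both classes guaranteed
    return make_dataset(X, y)
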