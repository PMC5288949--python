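import numpy as np
import pytest

from smklfs.dataset import ExpressionDataset
from smklfs.mkl import SolverSettings


@pytest.fixture
def settings() -> SolverSettings:
    return SolverSettings(C=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_dataset(X_sf: np.ndarray, y: np.ndarray, prefix: str = "f") -> ExpressionDataset:
    """Wrap a samples-by-features matrix and labels into an ExpressionDataset."""
    n, p = X_sf.shape
    return ExpressionDataset(
        X=X_sf.T,
        y=y,
        feature_ids=[f"{prefix}{j}" for j in range(p)],
        sample_ids=[f"s{i}" for i in range(n)],
    )


@pytest.fixture
def separable_ds(rng) -> ExpressionDataset:
    """40 samples, one feature tracking the labels plus four noise features."""
    y = np.array([1.0] * 20 + [-1.0] * 20)
    X = rng.normal(size=(40, 5))
    X[:, 0] = y + 0.05 * rng.normal(size=40)
    return make_dataset(X, y)
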