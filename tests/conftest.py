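import numpy as np
import pandas as pd
import pytest

from topostates.data import AbundanceTable, DistanceMatrix


def random_compositions(rng: np.random.Generator, n: int, m: int,
                        zeros: float = 0.0) -> np.ndarray:
    """Random compositions, optionally with a given fraction of zeros."""
    x = rng.dirichlet(np.ones(m), size=n)
    if zeros:
        mask = rng.random((n, m)) < zeros
        # never zero out a full row
        mask[np.arange(n), x.argmax(axis=1)] = False
        x = np.where(mask, 0.0, x)
        x /= x.sum(axis=1, keepdims=True)
    return x


def euclidean_dm(points: np.ndarray, ids=None) -> DistanceMatrix:
    """Distance matrix of Euclidean points (for geometry-based oracles)."""
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(ids=ids, d=d)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table():
    values = np.array([[2.0, 2.0], [1.0, 3.0], [4.0, 0.0]])
    samples = ["a", "b", "c"]
    meta = pd.DataFrame(
        {"subject": ["s1", "s1", "s2"], "time": [0.0, 1.0, 0.0]}, index=samples
    )
    return AbundanceTable(samples=samples, taxa=["t1", "t2"], values=values, meta=meta)


@pytest.fixture
def random_table(rng):
    n, m = 20, 6
    values = random_compositions(rng, n, m, zeros=0.2)
    samples = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {"subject": ["x"] * n, "time": np.arange(n, dtype=float)}, index=samples
    )
    return AbundanceTable(
        samples=samples, taxa=[f"t{j}" for j in range(m)], values=values, meta=meta
    )
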