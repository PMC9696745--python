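import numpy as np
import pytest

from bglm import ECDF, LabEventTable, build_ecdf


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_table():
    """Two codes with enough observations to sample from."""
    rows = [("A", float(v)) for v in range(5000)]
    rows += [("B", float(v) / 10) for v in range(300)]
    return LabEventTable.from_records(rows)


@pytest.fixture
def ecdf_123() -> ECDF:
    return build_ecdf(np.array([1.0, 2.0, 3.0]))


def random_sample_pair(rng, min_n=3, max_n=200):
    """A pair of samples mixing continuous and tie-heavy discrete values."""
    n_a, n_b = rng.integers(min_n, max_n + 1, size=2)
    if rng.random() < 0.5:
        a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n_a)
    else:
        a = rng.integers(0, 12, n_a).astype(float)
    if rng.random() < 0.5:
        b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n_b)
    else:
        b = rng.integers(0, 12, n_b).astype(float)
    return a, b


def brute_force_ks(a: np.ndarray, b: np.ndarray, n_grid: int = 20001) -> float:
    """Independent KS oracle: dense-grid sup of |F_a - F_b| over both samples.

    The grid is augmented with every sample value so the supremum of the
    step-function difference (attained at jump points) is always hit.
    """
    lo = min(a.min(), b.min()) - 1.0
    hi = max(a.max(), b.max()) + 1.0
    grid = np.union1d(np.linspace(lo, hi, n_grid), np.union1d(a, b))
    fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
    fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.abs(fa - fb).max())
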