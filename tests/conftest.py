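import math

import numpy as np
import pytest

from wspdrop import GrayHistogram, GrayImage


# ---------------------------------------------------------------------------
# Independent brute-force oracles (naive loops, no shared code with package)
# ---------------------------------------------------------------------------

def oracle_sigma2(p, k):
    """Between-class variance computed with explicit python loops."""
    P1 = sum(p[i] for i in range(k + 1))
    P2 = sum(p[i] for i in range(k + 1, 256))
    m = sum(i * p[i] for i in range(k + 1))
    mG = sum(i * p[i] for i in range(256))
    if P1 <= 0 or P2 <= 0:
        return 0.0
    return (mG * P1 - m) ** 2 / (P1 * P2)


def oracle_otsu(p):
    """Exhaustive argmax over all 256 thresholds; returns (k, max sigma2)."""
    values = [oracle_sigma2(p, k) for k in range(256)]
    best = max(values)
    tol = 1e-12 * max(best, 1.0)
    maximizers = [k for k, v in enumerate(values) if v >= best - tol]
    return math.floor(sum(maximizers) / len(maximizers)), best


def random_histogram(rng, max_levels=12, max_count=500):
    """A random occupied-level histogram with at least two distinct levels."""
    n_levels = int(rng.integers(2, max_levels + 1))
    levels = rng.choice(256, size=n_levels, replace=False)
    counts = np.zeros(256, dtype=np.int64)
    counts[levels] = rng.integers(1, max_count, size=n_levels)
    return counts


def hist_from_counts(counts):
    return GrayHistogram.from_counts(np.asarray(counts, dtype=np.int64))


def image_from(array, dpi=96.0):
    return GrayImage(pixels=np.asarray(array, dtype=np.uint8), dpi=dpi)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bimodal_hist():
    """100 pixels at gray 50 plus 100 pixels at gray 200."""
    counts = np.zeros(256, dtype=np.int64)
    counts[50] = 100
    counts[200] = 100
    return hist_from_counts(counts)


@pytest.fixture
def extremes_hist():
    """Half the pixels at 0, half at 255."""
    counts = np.zeros(256, dtype=np.int64)
    counts[0] = 50
    counts[255] = 50
    return hist_from_counts(counts)
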