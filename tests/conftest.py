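"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-derivations (double loops,
exhaustive permutation enumeration) kept independent of the library code
paths they check.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations

import numpy as np
import pytest

from imgram.classify import images_to_docs
from imgram.config import PipelineConfig
from imgram.synthetic_data import make_dataset, two_class_specs


def brute_force_tokens(cm, orders) -> Counter:
    """Token multiset by explicit double loop over rows and starts."""
    counter: Counter = Counter()
    rows, cols = np.asarray(cm).shape
    for r in range(rows):
        for n in sorted(orders):
            for start in range(cols - n + 1):
                counter["".join(cm[r, start : start + n])] += 1
    return counter


def exact_ranksum_p(x, y) -> float:
    """Two-sided Mann-Whitney p by full enumeration of group assignments.

    Enumerates every way to assign the pooled values to a group of
    len(x), computing the exact permutation distribution of the U
    statistic (ties handled by counting pairs with 1/2).
    """

    def u_stat(a, b):
        u = 0.0
        for xi in a:
            for yi in b:
                u += (xi > yi) + 0.5 * (xi == yi)
        return u

    pooled = list(x) + list(y)
    n = len(x)
    mean_u = len(x) * len(y) / 2.0
    obs = abs(u_stat(x, y) - mean_u)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(a, b) - mean_u) >= obs - 1e-12:
            hits += 1
    return hits / total


def random_char_matrix(rng, rows, cols):
    from imgram.encode import ALPHABET

    letters = np.array(list(ALPHABET))
    return letters[rng.integers(0, 16, size=(rows, cols))]


@pytest.fixture(scope="session")
def binary_dataset():
    """The separable two-class study fixture: 50 images/class, 32x32."""
    return make_dataset(two_class_specs(), 50, (32, 32), seed=7)


@pytest.fixture(scope="session")
def binary_docs(binary_dataset):
    return images_to_docs(list(binary_dataset.images))


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig(seed=7)
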