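"""Shared fixtures and independent reference (oracle) implementations.

The oracles deliberately avoid the package's fast paths: objectives by an
explicit double loop, greedy selection by a straightforward re-derivation
each step, exhaustive search by plain enumeration.  They exist so the
production code is checked against something that cannot share its bugs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from downselect import random_matrix, random_point_population, validate_matrix


# ---------------------------------------------------------------------------
# oracles

def naive_objective(values: np.ndarray, subset) -> float:
    """Sum of ln(d_ij) over unordered pairs, explicit double loop."""
    subset = list(subset)
    total = 0.0
    for a in range(len(subset)):
        for b in range(a + 1, len(subset)):
            d = values[subset[a], subset[b]]
            total += math.log(d) if d > 0 else -math.inf
    return total


def naive_best_pair(values: np.ndarray, mode: str = "dissimilar"):
    """Best off-diagonal pair by explicit scan with lexicographic tie-break."""
    n = values.shape[0]
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            if best is None:
                best = (i, j)
                continue
            v, bv = values[i, j], values[best]
            if (v > bv) if mode == "dissimilar" else (v < bv):
                best = (i, j)
    return best


def naive_greedy(values: np.ndarray, n: int, mode: str = "dissimilar"):
    """Step-by-step greedy re-derivation: at each step score every remaining
    candidate by its summed log-distance to the selected set, pick the
    extreme, smallest index on ties."""
    order = list(naive_best_pair(values, mode))
    while len(order) < n:
        best_idx, best_score = None, None
        for c in range(values.shape[0]):
            if c in order:
                continue
            score = sum(
                math.log(values[c, s]) if values[c, s] > 0 else -math.inf
                for s in order
            )
            if best_idx is None:
                best_idx, best_score = c, score
            elif mode == "dissimilar" and score > best_score:
                best_idx, best_score = c, score
            elif mode == "similar" and score < best_score:
                best_idx, best_score = c, score
        order.append(best_idx)
    return order


def naive_exact(values: np.ndarray, n: int, mode: str = "dissimilar"):
    """Plain enumeration of all subsets; first optimum in lexicographic
    order."""
    best_sub, best_val = None, None
    for sub in itertools.combinations(range(values.shape[0]), n):
        v = naive_objective(values, sub)
        if best_sub is None:
            best_sub, best_val = sub, v
        elif (v > best_val) if mode == "dissimilar" else (v < best_val):
            best_sub, best_val = sub, v
    return best_sub, best_val


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random rotation matrix and a random translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(0, 5, size=3)
    return R, t


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_points():
    """Deterministic 12-item Euclidean instance."""
    return random_point_population(12, 3, seed=42)


@pytest.fixture
def small_random_matrix():
    """Deterministic 10-item non-metric instance."""
    return random_matrix(10, seed=7)


@pytest.fixture
def duplicate_matrix():
    """Matrix where item 3 duplicates item 0 (zero distance between them)."""
    m = random_point_population(6, 2, seed=5).values.copy()
    m[0, 3] = m[3, 0] = 0.0
    return validate_matrix(m)
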