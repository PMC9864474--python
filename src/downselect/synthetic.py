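"""Seeded generators of test populations.

Every generator is a pure function of its arguments: the RNG stream is
derived from the user seed through ``numpy.random.SeedSequence`` with a
per-generator spawn key (points=0, matrix=1, ensemble=2), so adding new
generators never perturbs existing fixtures and the same call always
reproduces bit-identical output.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .conformer_io import Conformer, ConformerEnsemble
from .matrix_core import DissimilarityMatrix, validate_matrix

__all__ = [
    "random_point_population",
    "random_matrix",
    "perturbed_ensemble",
]

_STREAM_POINTS = 0
_STREAM_MATRIX = 1
_STREAM_ENSEMBLE = 2

_ELEMENTS = ("C", "N", "O", "H")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def random_point_population(N: int, dim: int, seed: int) -> DissimilarityMatrix:
    """Euclidean distance matrix of N points drawn uniformly from the unit
    hypercube in ``dim`` dimensions.  Always a metric."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = _rng(seed, _STREAM_POINTS)
    points = rng.random((N, dim))
    values = squareform(pdist(points))
    return validate_matrix(
        values,
        metadata={"kind": "points", "N": N, "dim": dim, "seed": seed},
    )


def random_matrix(
    N: int,
    seed: int,
    distribution: str = "uniform",
    low: float = 0.1,
    high: float = 1.0,
    allow_zeros: bool = False,
    zero_prob: float = 0.0,
) -> DissimilarityMatrix:
    """Symmetric matrix with i.i.d. upper-triangle draws (non-metric stress
    generator).

    The default distribution is uniform on (low, high] with low > 0.  With
    ``allow_zeros`` a fraction ``zero_prob`` of the entries is replaced by an
    exact 0 (a point mass for duplicate-handling tests); without the flag
    any parameterization that can produce non-positive draws is rejected.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if distribution != "uniform":
        raise ValueError(f"unknown distribution {distribution!r}")
    if not allow_zeros and low <= 0:
        raise ValueError(
            "distribution support must be strictly positive unless allow_zeros is set"
        )
    if allow_zeros and not 0.0 <= zero_prob <= 1.0:
        raise ValueError("zero_prob must lie in [0, 1]")
    rng = _rng(seed, _STREAM_MATRIX)
    k = N * (N - 1) // 2
    # uniform on (low, high]: flip the half-open side of random()
    tri = high - rng.random(k) * (high - low)
    if allow_zeros and zero_prob > 0:
        tri[rng.random(k) < zero_prob] = 0.0
    values = np.zeros((N, N))
    iu, ju = np.triu_indices(N, k=1)
    values[iu, ju] = tri
    values[ju, iu] = tri
    return validate_matrix(
        values,
        metadata={
            "kind": "matrix",
            "N": N,
            "distribution": distribution,
            "low": low,
            "high": high,
            "allow_zeros": allow_zeros,
            "zero_prob": zero_prob,
            "seed": seed,
        },
    )


def perturbed_ensemble(
    atom_count: int, K: int, sigma: float, seed: int
) -> ConformerEnsemble:
    """K conformers built as one random base structure plus i.i.d. Gaussian
    coordinate noise.

    The base structure has ``atom_count`` atoms placed uniformly in a 10 Å
    box with elements drawn from {C, N, O, H}; each conformer displaces
    every coordinate by N(0, sigma^2).  For two independently perturbed
    copies each coordinate difference is N(0, 2 sigma^2), so the expected
    squared (unsuperposed) RMSD is 6 sigma^2 regardless of atom count.
    """
    if atom_count < 1:
        raise ValueError("atom_count must be >= 1")
    if K < 2:
        raise ValueError("K must be >= 2")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = _rng(seed, _STREAM_ENSEMBLE)
    base = rng.random((atom_count, 3)) * 10.0
    elements = tuple(_ELEMENTS[i] for i in rng.integers(0, len(_ELEMENTS), atom_count))
    conformers = tuple(
        Conformer(
            id=f"conf_{k}",
            elements=elements,
            coords=base + rng.normal(0.0, sigma, size=(atom_count, 3)),
        )
        for k in range(K)
    )
    return ConformerEnsemble(conformers=conformers, source="synthetic")
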