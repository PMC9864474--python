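"""Pairwise dissimilarity matrices and the log-sum set objective.

A population of N items with a pairwise dissimilarity d_ij is held as a
dense symmetric N x N matrix with a zero diagonal.  Subset quality is the
sum of ln(d_ij) over all unordered pairs inside the subset ("log-sum"),
which equals the log of the product of pairwise distances but stays
representable for arbitrarily many items.  Zero distances (exact
duplicates) map to -inf and propagate through sums, so a subset containing
a duplicate pair scores -inf rather than raising.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DissimilarityMatrix",
    "LogDissimilarityMatrix",
    "SubsetObjective",
    "validate_matrix",
    "log_transform",
    "set_objective",
    "search_space_size",
    "mean_random_objective",
    "write_matrix",
    "read_matrix",
]

DEFAULT_SYMMETRY_TOL = 1e-8

_MAGIC = b"SDSM"
_BINARY_VERSION = 1


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Validated symmetric matrix of pairwise dissimilarities.

    Attributes
    ----------
    values : (N, N) float64 array, symmetric, zero diagonal, entries >= 0.
    labels : optional tuple of N item identifiers.
    metadata : free-form provenance (metric, generator parameters, ...).
    """

    values: np.ndarray
    labels: tuple[str, ...] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def label_of(self, index: int) -> str:
        if self.labels is not None:
            return self.labels[index]
        return str(index)


@dataclass(frozen=True)
class LogDissimilarityMatrix:
    """Element-wise natural log of a dissimilarity matrix.

    Off-diagonal entry (i, j) is ln(d_ij); a zero distance becomes -inf.
    The diagonal carries NaN, the "cannot be selected" sentinel, never a
    finite value.
    """

    values: np.ndarray

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SubsetObjective:
    """Scalar log-sum objective of a subset: sum of ln(d_ij), each unordered
    pair counted exactly once.  -inf if any pair inside the subset has
    distance zero."""

    value: float

    def __float__(self) -> float:
        return self.value


def validate_matrix(
    raw: np.ndarray | Sequence[Sequence[float]],
    symmetry_tol: float = DEFAULT_SYMMETRY_TOL,
    labels: Sequence[str] | None = None,
    metadata: dict | None = None,
) -> DissimilarityMatrix:
    """Validate a raw square array as a dissimilarity matrix.

    Asymmetries within ``symmetry_tol`` (relative to max(1, |entry|)) are
    averaged away; the diagonal is forced to exactly zero provided no
    diagonal entry exceeds the tolerance in absolute value.

    Raises
    ------
    ValueError
        Non-square input, N < 2, negative or non-finite entries, asymmetry
        or diagonal magnitude beyond tolerance, label-count mismatch.
    """
    a = np.asarray(raw, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"matrix must be square, got shape {a.shape}")
    n = a.shape[0]
    if n < 2:
        raise ValueError("matrix must have at least 2 items")
    if not np.all(np.isfinite(a)):
        raise ValueError("matrix contains non-finite entries")
    if np.any(a < 0):
        raise ValueError("matrix contains negative entries")

    diag = np.abs(np.diagonal(a))
    if np.any(diag > symmetry_tol):
        i = int(np.argmax(diag))
        raise ValueError(f"diagonal entry [{i},{i}] = {a[i, i]!r} is not zero")

    asym = np.abs(a - a.T)
    tol = symmetry_tol * np.maximum(1.0, np.abs(a))
    if np.any(asym > tol):
        i, j = np.unravel_index(int(np.argmax(asym - tol)), a.shape)
        raise ValueError(
            f"asymmetry at [{i},{j}]: {a[i, j]!r} vs {a[j, i]!r} "
            f"exceeds tolerance {symmetry_tol}"
        )

    sym = (a + a.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    sym.flags.writeable = False

    lab: tuple[str, ...] | None = None
    if labels is not None:
        lab = tuple(str(x) for x in labels)
        if len(lab) != n:
            raise ValueError(f"expected {n} labels, got {len(lab)}")
    return DissimilarityMatrix(values=sym, labels=lab, metadata=dict(metadata or {}))


def log_transform(m: DissimilarityMatrix) -> LogDissimilarityMatrix:
    """Natural log of every off-diagonal entry; zero distances become -inf,
    the diagonal becomes NaN (masked)."""
    with np.errstate(divide="ignore"):
        logv = np.log(m.values)
    np.fill_diagonal(logv, np.nan)
    logv.flags.writeable = False
    return LogDissimilarityMatrix(values=logv)


def _check_subset(n: int, subset: Sequence[int]) -> np.ndarray:
    idx = np.asarray(subset, dtype=np.intp)
    if idx.ndim != 1 or idx.size < 2:
        raise ValueError("subset must contain at least 2 indices")
    if np.any(idx < 0) or np.any(idx >= n):
        raise ValueError(f"subset index out of range [0, {n})")
    if np.unique(idx).size != idx.size:
        raise ValueError("subset contains duplicate indices")
    # canonical order: makes the floating-point sum (and hence the objective)
    # exactly permutation-invariant
    return np.sort(idx)


def set_objective(m: DissimilarityMatrix, subset: Sequence[int]) -> SubsetObjective:
    """Log-sum objective of ``subset``: sum over unordered pairs {i, j} of
    ln(d_ij).  Order-insensitive; -inf if any inside pair has distance 0."""
    idx = _check_subset(m.size, subset)
    sub = m.values[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(idx.size, k=1)
    with np.errstate(divide="ignore"):
        return SubsetObjective(value=float(np.sum(np.log(sub[iu, ju]))))


def set_objective_from_log(L: LogDissimilarityMatrix, subset: Sequence[int]) -> float:
    """Same objective computed from a pre-logged matrix (fast path for
    selectors that hold the log form already)."""
    idx = _check_subset(L.size, subset)
    sub = L.values[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(idx.size, k=1)
    return float(np.sum(sub[iu, ju]))


def search_space_size(N: int, n: int) -> int:
    """Number of distinct n-subsets of an N-item population: the binomial
    coefficient C(N, n), exact arbitrary-precision integer."""
    if N < 0:
        raise ValueError("N must be nonnegative")
    if n < 0 or n > N:
        raise ValueError(f"n must lie in [0, {N}], got {n}")
    return math.comb(N, n)


def mean_random_objective(m: DissimilarityMatrix, n: int) -> float:
    """Expected log-sum objective of a uniformly random n-subset.

    By linearity of expectation every unordered pair lands in the subset
    with the same probability, so the expectation reduces to
    C(n, 2) * mean(ln d_ij over all off-diagonal pairs).
    """
    if not 2 <= n <= m.size:
        raise ValueError(f"n must lie in [2, {m.size}], got {n}")
    iu, ju = np.triu_indices(m.size, k=1)
    d = m.values[iu, ju]
    if np.any(d == 0):
        raise ValueError(
            "matrix has a zero off-diagonal distance: the expected objective "
            "is -inf and not meaningful"
        )
    return math.comb(n, 2) * float(np.mean(np.log(d)))


# ---------------------------------------------------------------------------
# persistence

def write_matrix(m: DissimilarityMatrix, path: str | Path, format: str = "text") -> None:
    """Write a matrix as delimited text (labelled, full-precision repr) or in
    the compact binary form (magic ``SDSM``, version byte, uint64 N, strict
    upper triangle as little-endian float64)."""
    path = Path(path)
    if format == "text":
        labels = [m.label_of(i) for i in range(m.size)]
        with path.open("w") as fh:
            fh.write("\t".join(["#"] + labels) + "\n")
            for i in range(m.size):
                row = [repr(float(v)) for v in m.values[i]]
                fh.write("\t".join([labels[i]] + row) + "\n")
    elif format == "binary":
        iu, ju = np.triu_indices(m.size, k=1)
        tri = np.ascontiguousarray(m.values[iu, ju], dtype="<f8")
        with path.open("wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<B", _BINARY_VERSION))
            fh.write(struct.pack("<Q", m.size))
            fh.write(tri.tobytes())
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def read_matrix(path: str | Path, symmetry_tol: float = DEFAULT_SYMMETRY_TOL) -> DissimilarityMatrix:
    """Read a matrix written by :func:`write_matrix`; the binary magic is
    sniffed, otherwise the file is parsed as tab- or comma-delimited text.
    Validation is applied on read."""
    path = Path(path)
    with path.open("rb") as fh:
        head = fh.read(4)
    if head == _MAGIC:
        return _read_binary(path, symmetry_tol)
    return _read_text(path, symmetry_tol)


def _read_binary(path: Path, symmetry_tol: float) -> DissimilarityMatrix:
    with path.open("rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise ValueError(f"bad magic bytes {magic!r}")
        ver = fh.read(1)
        if len(ver) != 1 or ver[0] != _BINARY_VERSION:
            raise ValueError(f"unsupported binary matrix version {ver!r}")
        (n,) = struct.unpack("<Q", fh.read(8))
        if n < 2:
            raise ValueError("binary matrix must have N >= 2")
        k = n * (n - 1) // 2
        payload = fh.read()
    expected = 8 * k
    if len(payload) != expected:
        raise ValueError(
            f"truncated or oversized binary matrix: expected {expected} payload "
            f"bytes for N={n}, got {len(payload)}"
        )
    tri = np.frombuffer(payload, dtype="<f8")
    full = np.zeros((n, n), dtype=np.float64)
    iu, ju = np.triu_indices(n, k=1)
    full[iu, ju] = tri
    full[ju, iu] = tri
    return validate_matrix(full, symmetry_tol=symmetry_tol, metadata={"source": str(path)})


def _read_text(path: Path, symmetry_tol: float) -> DissimilarityMatrix:
    lines = [ln.rstrip("\n") for ln in path.open() if ln.strip()]
    if len(lines) < 3:
        raise ValueError("text matrix must have a header row and >= 2 data rows")
    delim = "\t" if "\t" in lines[0] else ","
    header = lines[0].split(delim)
    labels = header[1:]
    n = len(labels)
    rows = []
    row_labels = []
    for ln in lines[1:]:
        parts = ln.split(delim)
        if len(parts) != n + 1:
            raise ValueError(f"row has {len(parts) - 1} cells, expected {n}")
        row_labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    if len(rows) != n:
        raise ValueError(f"expected {n} data rows, got {len(rows)}")
    if row_labels != labels:
        raise ValueError("row labels do not match column labels")
    return validate_matrix(
        np.array(rows, dtype=np.float64),
        symmetry_tol=symmetry_tol,
        labels=labels,
        metadata={"source": str(path)},
    )
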