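"""Subset selection: greedy log-sum downselection, Monte Carlo best-of-k
sampling, and exhaustive exact search.

All three methods optimize the same objective — the sum of ln(d_ij) over
all unordered pairs inside the chosen subset — in either ``dissimilar``
(maximize) or ``similar`` (minimize) mode, with deterministic tie-breaking
by smallest index / lexicographically smallest subset.

The greedy method keeps a single "summation array" holding, for every
unselected item, the running sum of log-distances to everything selected
so far.  Each step picks the extreme unmasked entry, adds the winner's
log-row into the array, and masks the winner with NaN.  Because the chosen
prefix never changes, the size-n solution nests inside the size-(n+1)
solution, and one full pass yields the solution for every n at O(N^2)
total cost.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np

from .matrix_core import (
    DissimilarityMatrix,
    LogDissimilarityMatrix,
    SubsetObjective,
    log_transform,
    search_space_size,
    set_objective,
)

__all__ = [
    "SelectionResult",
    "select_initial_pair",
    "sds_select",
    "sds_select_all",
    "mc_select",
    "exact_select",
    "EXACT_GUARD_DEFAULT",
]

Mode = Literal["dissimilar", "similar"]

EXACT_GUARD_DEFAULT = 10_000_000


def _check_mode(mode: str) -> None:
    if mode not in ("dissimilar", "similar"):
        raise ValueError(f"mode must be 'dissimilar' or 'similar', got {mode!r}")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one selection run.

    ``order`` is the selection order for the greedy method; for Monte Carlo
    and exact search the chosen subset is reported sorted ascending because
    no per-item order is meaningful.  ``step_scores`` and
    ``objective_trace`` are greedy-only: the summation-array value at which
    each item from the third onward was taken, and the objective of every
    prefix of length 2..n.
    """

    method: Literal["sds", "monte_carlo", "exact"]
    mode: Mode
    order: tuple[int, ...]
    objective: SubsetObjective
    step_scores: tuple[float, ...] = ()
    objective_trace: tuple[float, ...] = ()
    iterations: int | None = None
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.order)

    def indices(self) -> tuple[int, ...]:
        """Selected indices sorted ascending (set identity, not order)."""
        return tuple(sorted(self.order))

    def summary(self) -> dict:
        """Machine-readable summary (plain key-value types only)."""
        out = {
            "method": self.method,
            "mode": self.mode,
            "n": self.n,
            "objective": self.objective.value,
            "indices": list(self.indices()),
        }
        if self.method == "sds":
            out["order"] = list(self.order)
        if self.iterations is not None:
            out["iterations"] = self.iterations
        if self.seed is not None:
            out["seed"] = self.seed
        return out

    def report(self, m: DissimilarityMatrix | None = None) -> str:
        """Human-readable per-selection report: rank, index, label, step
        score, prefix objective."""
        lines = [
            f"# method={self.method} mode={self.mode} n={self.n} "
            f"objective={self.objective.value!r}"
            + (f" iterations={self.iterations}" if self.iterations is not None else "")
            + (f" seed={self.seed}" if self.seed is not None else ""),
            "rank\tindex\tlabel\tstep_score\tprefix_objective",
        ]
        for rank, idx in enumerate(self.order):
            label = m.label_of(idx) if m is not None else str(idx)
            if self.method == "sds":
                score = repr(self.step_scores[rank - 2]) if rank >= 2 else ""
                pref = repr(self.objective_trace[rank - 1]) if rank >= 1 else ""
            else:
                score, pref = "", ""
            lines.append(f"{rank}\t{idx}\t{label}\t{score}\t{pref}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# greedy

def select_initial_pair(L: LogDissimilarityMatrix, mode: Mode = "dissimilar") -> tuple[int, int]:
    """The exactly optimal pair: argmax (dissimilar) or argmin (similar) of
    d_ij over off-diagonal pairs, ties broken by lexicographically smallest
    (i, j) with i < j."""
    _check_mode(mode)
    n = L.size
    if n < 2:
        raise ValueError("need at least 2 items")
    work = L.values.copy()
    iu = np.tril_indices(n, k=0)
    if mode == "dissimilar":
        work[iu] = -np.inf
        flat = int(np.argmax(work))  # row-major first max = lexicographic tie-break
    else:
        work[iu] = np.inf
        # -inf (zero distance) entries are legitimately the most similar
        flat = int(np.argmin(work))
    i, j = divmod(flat, n)
    return i, j


def _greedy_run(
    L: LogDissimilarityMatrix, n: int, mode: Mode
) -> tuple[list[int], list[float]]:
    """Shared greedy engine: returns (selection order, step scores for items
    3..n).  Masked (already-selected) entries carry NaN; -inf entries are
    valid candidates but lose to any finite score in dissimilar mode."""
    i0, j0 = select_initial_pair(L, mode)
    order = [i0, j0]
    if n == 2:
        return order, []

    summation = L.values[i0] + L.values[j0]
    summation[[i0, j0]] = np.nan
    pick_extreme = _nan_argmax_first if mode == "dissimilar" else _nan_argmin_first

    step_scores: list[float] = []
    for _ in range(n - 2):
        k = pick_extreme(summation)
        step_scores.append(float(summation[k]))
        order.append(k)
        summation = summation + L.values[k]
        summation[k] = np.nan
        summation[order[:-1]] = np.nan  # keep earlier picks masked after the add
    return order, step_scores


def _nan_argmax_first(a: np.ndarray) -> int:
    """Index of the largest non-NaN value; first occurrence wins ties.
    Works when every unmasked entry is -inf (returns the smallest index)."""
    valid = ~np.isnan(a)
    if not valid.any():
        raise ValueError("no unmasked candidates remain")
    idx = np.flatnonzero(valid)
    return int(idx[np.argmax(a[idx])])


def _nan_argmin_first(a: np.ndarray) -> int:
    valid = ~np.isnan(a)
    if not valid.any():
        raise ValueError("no unmasked candidates remain")
    idx = np.flatnonzero(valid)
    return int(idx[np.argmin(a[idx])])


def _greedy_result(
    m: DissimilarityMatrix, L: LogDissimilarityMatrix, order: list[int], step_scores: list[float], mode: Mode
) -> SelectionResult:
    # prefix objectives follow from the greedy increments: each step score is
    # exactly the objective gain of adding that item
    trace = [float(L.values[order[0], order[1]])]
    for s in step_scores:
        trace.append(trace[-1] + s)
    # final objective is re-scored through the same summation path the other
    # methods use, so cross-method comparisons are rounding-consistent
    return SelectionResult(
        method="sds",
        mode=mode,
        order=tuple(order),
        step_scores=tuple(step_scores),
        objective_trace=tuple(trace),
        objective=set_objective(m, order),
    )


def sds_select(m: DissimilarityMatrix, n: int, mode: Mode = "dissimilar") -> SelectionResult:
    """Greedy downselection of ``n`` items.

    Starts from the exactly optimal pair, then repeatedly takes the item
    whose summed log-distance to everything already selected is largest
    (dissimilar mode) or smallest (similar mode).
    """
    _check_mode(mode)
    if not 2 <= n <= m.size:
        raise ValueError(f"n must lie in [2, {m.size}], got {n}")
    L = log_transform(m)
    order, scores = _greedy_run(L, n, mode)
    return _greedy_result(m, L, order, scores, mode)


def sds_select_all(m: DissimilarityMatrix, mode: Mode = "dissimilar") -> SelectionResult:
    """One full greedy pass over all N items; the length-k prefix of the
    returned order is exactly the greedy solution of size k.  O(N^2) time,
    O(N) auxiliary space beyond the matrix."""
    _check_mode(mode)
    L = log_transform(m)
    order, scores = _greedy_run(L, m.size, mode)
    return _greedy_result(m, L, order, scores, mode)


# ---------------------------------------------------------------------------
# Monte Carlo baseline

def _score_subset_block(logv: np.ndarray, subsets: np.ndarray) -> np.ndarray:
    """Objectives of a (B, n) block of subsets against the logged matrix:
    vectorized gather over the n(n-1)/2 position pairs."""
    n = subsets.shape[1]
    total = np.zeros(subsets.shape[0])
    for a in range(n - 1):
        for b in range(a + 1, n):
            total += logv[subsets[:, a], subsets[:, b]]
    return total


def mc_select(
    m: DissimilarityMatrix,
    n: int,
    iterations: int,
    seed: int,
    mode: Mode = "dissimilar",
) -> SelectionResult:
    """Best of ``iterations`` uniform random n-subsets.

    Subsets are drawn independently (repeats across iterations allowed),
    scored with the log-sum objective, and the best is returned — max in
    dissimilar mode, min in similar mode.  Deterministic for a fixed seed;
    a prefix of the iteration budget under the same seed scores the same
    initial draws, so the best-so-far objective is monotone in the budget.
    """
    _check_mode(mode)
    if not 2 <= n <= m.size:
        raise ValueError(f"n must lie in [2, {m.size}], got {n}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    rng = np.random.default_rng(seed)
    draws = np.empty((iterations, n), dtype=np.intp)
    for it in range(iterations):
        draws[it] = rng.choice(m.size, size=n, replace=False)

    with np.errstate(divide="ignore"):
        logv = np.log(m.values)
    np.fill_diagonal(logv, 0.0)  # diagonal never gathered (pairs are distinct)

    best_val = -np.inf if mode == "dissimilar" else np.inf
    best_sub: tuple[int, ...] | None = None
    block = 65536
    for start in range(0, iterations, block):
        sub = draws[start : start + block]
        scores = _score_subset_block(logv, sub)
        for it in range(sub.shape[0]):
            v = scores[it]
            better = v > best_val if mode == "dissimilar" else v < best_val
            if best_sub is None or better:
                best_val, best_sub = v, tuple(int(x) for x in sorted(sub[it]))
            elif v == best_val and best_sub is not None:
                cand = tuple(int(x) for x in sorted(sub[it]))
                if cand < best_sub:
                    best_sub = cand
    assert best_sub is not None
    return SelectionResult(
        method="monte_carlo",
        mode=mode,
        order=best_sub,
        objective=set_objective(m, best_sub),
        iterations=iterations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# exhaustive baseline

def _combination_blocks(N: int, n: int, block: int) -> Iterator[np.ndarray]:
    it = itertools.combinations(range(N), n)
    while True:
        chunk = list(itertools.islice(it, block))
        if not chunk:
            return
        yield np.array(chunk, dtype=np.intp)


def exact_select(
    m: DissimilarityMatrix,
    n: int,
    mode: Mode = "dissimilar",
    guard: int = EXACT_GUARD_DEFAULT,
    override_guard: bool = False,
) -> SelectionResult:
    """Exhaustive optimum over all C(N, n) subsets, enumerated in
    lexicographic order; the first subset attaining the optimal objective
    wins, so the result is deterministic.

    Refuses to run when C(N, n) exceeds ``guard`` unless
    ``override_guard=True`` — the search space grows super-exponentially
    and is hopeless long before it stops fitting in an integer.
    """
    _check_mode(mode)
    if not 2 <= n <= m.size:
        raise ValueError(f"n must lie in [2, {m.size}], got {n}")
    count = search_space_size(m.size, n)
    if count > guard and not override_guard:
        raise ValueError(
            f"exhaustive search over C({m.size}, {n}) = {count} subsets exceeds "
            f"the guard of {guard}; pass override_guard=True to force it"
        )

    with np.errstate(divide="ignore"):
        logv = np.log(m.values)
    np.fill_diagonal(logv, 0.0)

    sign = 1.0 if mode == "dissimilar" else -1.0
    best_val = -np.inf
    best_sub: tuple[int, ...] | None = None
    for sub in _combination_blocks(m.size, n, 200_000):
        scores = sign * _score_subset_block(logv, sub)
        k = int(np.argmax(scores))  # first max in a block = lexicographic winner
        if best_sub is None or scores[k] > best_val:
            best_val = float(scores[k])
            best_sub = tuple(int(x) for x in sub[k])
    assert best_sub is not None
    return SelectionResult(
        method="exact",
        mode=mode,
        order=best_sub,
        objective=set_objective(m, best_sub),
    )
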