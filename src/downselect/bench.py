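"""Benchmark harness comparing the greedy selector against the Monte Carlo
and exhaustive baselines on one matrix, emitting tabular reports."""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .matrix_core import DissimilarityMatrix, mean_random_objective, set_objective
from .selectors import EXACT_GUARD_DEFAULT, exact_select, mc_select, sds_select

__all__ = ["BenchmarkReport", "bench_mc", "bench_exact"]


@dataclass
class BenchmarkReport:
    """Rows of (method, mode, n, objective, ...) for one benchmark instance.

    Every row's objective can be reproduced by re-scoring its ``indices``
    with :func:`set_objective`; wall times are informational only.
    """

    instance: dict
    rows: list[dict] = field(default_factory=list)

    def add_row(self, **row) -> None:
        self.rows.append(row)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_tsv(self) -> str:
        header = "# " + " ".join(f"{k}={v}" for k, v in sorted(self.instance.items()))
        if not self.rows:
            return header + "\n"
        return header + "\n" + self.to_dataframe().to_csv(sep="\t", index=False)

    def verify(self, m: DissimilarityMatrix) -> None:
        """Assert each row's objective matches a re-score of its indices."""
        for row in self.rows:
            if row.get("indices") is None:
                continue
            rescored = set_objective(m, row["indices"]).value
            if rescored != row["objective"]:
                raise AssertionError(
                    f"row {row['method']}/n={row['n']}: stored objective "
                    f"{row['objective']!r} != re-scored {rescored!r}"
                )


def bench_mc(
    matrix: DissimilarityMatrix,
    n_values: Sequence[int],
    iterations: int,
    seed: int,
    mode: str = "dissimilar",
) -> BenchmarkReport:
    """Greedy vs best-of-k Monte Carlo for each requested set size; the
    winner per n is recorded (greedy wins ties)."""
    report = BenchmarkReport(
        instance={
            "benchmark": "mc",
            "N": matrix.size,
            "iterations": iterations,
            "seed": seed,
            "mode": mode,
        }
    )
    for n in n_values:
        t0 = time.perf_counter()
        sds = sds_select(matrix, n, mode=mode)
        t_sds = time.perf_counter() - t0
        t0 = time.perf_counter()
        mc = mc_select(matrix, n, iterations=iterations, seed=seed, mode=mode)
        t_mc = time.perf_counter() - t0
        if mode == "dissimilar":
            winner = "sds" if sds.objective.value >= mc.objective.value else "monte_carlo"
        else:
            winner = "sds" if sds.objective.value <= mc.objective.value else "monte_carlo"
        report.add_row(
            method="sds", mode=mode, n=n, objective=sds.objective.value,
            indices=list(sds.indices()), iterations=None, seed=None,
            wall_time_s=t_sds, winner=winner,
        )
        report.add_row(
            method="monte_carlo", mode=mode, n=n, objective=mc.objective.value,
            indices=list(mc.indices()), iterations=iterations, seed=seed,
            wall_time_s=t_mc, winner=winner,
        )
    return report


def bench_exact(
    matrix: DissimilarityMatrix,
    n: int,
    guard: int = EXACT_GUARD_DEFAULT,
    override_guard: bool = False,
) -> BenchmarkReport:
    """Exhaustive optimum vs greedy vs the analytic random-subset mean vs
    the exhaustive minimum (most-similar) reference for one set size.

    Sanity-asserts the orderings exact >= greedy and mean >= minimum.
    """
    report = BenchmarkReport(
        instance={"benchmark": "exact", "N": matrix.size, "n": n}
    )
    t0 = time.perf_counter()
    exact = exact_select(matrix, n, mode="dissimilar", guard=guard, override_guard=override_guard)
    t_exact = time.perf_counter() - t0
    t0 = time.perf_counter()
    sds = sds_select(matrix, n, mode="dissimilar")
    t_sds = time.perf_counter() - t0
    mean_obj = mean_random_objective(matrix, n)
    minimum = exact_select(matrix, n, mode="similar", guard=guard, override_guard=override_guard)

    if exact.objective.value < sds.objective.value:
        raise AssertionError("exhaustive optimum scored below the greedy solution")
    if mean_obj < minimum.objective.value:
        raise AssertionError("random-subset mean scored below the exhaustive minimum")

    gap = exact.objective.value - sds.objective.value
    report.add_row(
        method="exact", mode="dissimilar", n=n, objective=exact.objective.value,
        indices=list(exact.indices()), wall_time_s=t_exact, gap_to_exact=0.0,
    )
    report.add_row(
        method="sds", mode="dissimilar", n=n, objective=sds.objective.value,
        indices=list(sds.indices()), wall_time_s=t_sds, gap_to_exact=gap,
    )
    report.add_row(
        method="mean_random", mode="dissimilar", n=n, objective=mean_obj,
        indices=None, wall_time_s=None, gap_to_exact=exact.objective.value - mean_obj,
    )
    report.add_row(
        method="exact_minimum", mode="similar", n=n, objective=minimum.objective.value,
        indices=list(minimum.indices()), wall_time_s=None,
        gap_to_exact=exact.objective.value - minimum.objective.value,
    )
    return report
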