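import math

import numpy as np
import pytest

from downselect.matrix_core import log_transform, set_objective, validate_matrix
from downselect.selectors import (
    exact_select,
    mc_select,
    sds_select,
    sds_select_all,
    select_initial_pair,
)
from downselect.synthetic import random_matrix, random_point_population

from conftest import naive_best_pair, naive_exact, naive_greedy, naive_objective


def points_matrix(positions):
    pts = np.asarray(positions, dtype=float)
    return validate_matrix(np.abs(pts[:, None] - pts[None, :]))


class TestInitialPair:
    def test_unique_argmax(self):
        values = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        L = log_transform(validate_matrix(values))
        assert select_initial_pair(L, "dissimilar") == (1, 2)
        assert select_initial_pair(L, "similar") == (0, 1)

    def test_lexicographic_tie_break(self):
        values = np.full((4, 4), 2.0)
        np.fill_diagonal(values, 0.0)
        L = log_transform(validate_matrix(values))
        assert select_initial_pair(L, "dissimilar") == (0, 1)
        assert select_initial_pair(L, "similar") == (0, 1)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("mode", ["dissimilar", "similar"])
    def test_matches_pair_scan_oracle(self, seed, mode):
        m = random_matrix(12, seed=seed)
        L = log_transform(m)
        assert select_initial_pair(L, mode) == naive_best_pair(m.values, mode)

    def test_bad_mode(self, small_points):
        with pytest.raises(ValueError, match="mode"):
            select_initial_pair(log_transform(small_points), "weird")


class TestGreedySelect:
    def test_hand_traceable_instance(self):
        # 1-D points 0, 1, 10, 11: initial pair (0, 3) with d = 11, then
        # items 1 and 2 tie at ln 1 + ln 10 and the smaller index wins
        m = points_matrix([0.0, 1.0, 10.0, 11.0])
        r = sds_select(m, 3)
        assert r.order == (0, 3, 1)
        assert r.step_scores[0] == pytest.approx(math.log(1) + math.log(10))

    def test_n2_equals_initial_pair_and_exact(self, small_random_matrix):
        r = sds_select(small_random_matrix, 2)
        assert r.order == select_initial_pair(log_transform(small_random_matrix))
        assert r.indices() == exact_select(small_random_matrix, 2).indices()

    @pytest.mark.parametrize("mode", ["dissimilar", "similar"])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_step_by_step_oracle(self, seed, mode):
        m = random_point_population(15, 3, seed=seed)
        for n in (3, 6, 10, 15):
            assert list(sds_select(m, n, mode=mode).order) == naive_greedy(
                m.values, n, mode
            )

    def test_duplicate_never_selected_early(self, duplicate_matrix):
        # item 3 duplicates item 0: once 0 is in, 3's score is -inf
        r = sds_select_all(duplicate_matrix)
        order = list(r.order)
        # once either of the zero-distance pair is selected, the other scores
        # -inf and must lose to every finite candidate, i.e. go last
        assert max(order.index(0), order.index(3)) == len(order) - 1

    def test_greedy_increment_identity(self):
        m = random_matrix(20, seed=13)
        for n in range(3, 21):
            r = sds_select(m, n)
            for k in range(1, len(r.objective_trace)):
                inc = r.objective_trace[k] - r.objective_trace[k - 1]
                assert inc == pytest.approx(r.step_scores[k - 1], rel=1e-9)

    def test_objective_matches_rescore(self, small_points):
        r = sds_select(small_points, 8)
        assert r.objective.value == pytest.approx(
            set_objective(small_points, r.order).value, rel=1e-12
        )

    def test_invalid_n(self, small_points):
        with pytest.raises(ValueError):
            sds_select(small_points, 1)
        with pytest.raises(ValueError):
            sds_select(small_points, small_points.size + 1)


class TestGreedySelectAll:
    def test_prefixes_equal_fixed_n_runs(self):
        m = random_point_population(5, 2, seed=3)
        full = sds_select_all(m)
        for k in range(2, 5):
            assert full.order[:k] == sds_select(m, k).order

    def test_exhaustion(self, small_points):
        r = sds_select_all(small_points)
        assert sorted(r.order) == list(range(small_points.size))

    def test_prefix_objectives_recompute(self):
        m = random_point_population(50, 3, seed=8)
        r = sds_select_all(m)
        for k in (2, 7, 23, 50):
            assert r.objective_trace[k - 2] == pytest.approx(
                set_objective(m, r.order[:k]).value, rel=1e-9
            )

    @pytest.mark.parametrize("seed", range(3))
    def test_nesting_property(self, seed):
        m = random_matrix(18, seed=seed)
        full = sds_select_all(m)
        for k in range(2, 19):
            assert full.order[:k] == sds_select(m, k).order


class TestMonteCarlo:
    def test_best_of_one(self, small_points):
        r = mc_select(small_points, 4, iterations=1, seed=99)
        rng = np.random.default_rng(99)
        drawn = tuple(sorted(rng.choice(small_points.size, size=4, replace=False)))
        assert r.indices() == drawn
        assert r.objective.value == pytest.approx(
            naive_objective(small_points.values, drawn)
        )

    def test_finds_exact_optimum_tiny_population(self):
        # C(6, 3) = 20 subsets; 10,000 draws miss one with probability ~0
        m = random_point_population(6, 3, seed=17)
        mc = mc_select(m, 3, iterations=10000, seed=5)
        best_sub, best_val = naive_exact(m.values, 3)
        assert mc.indices() == best_sub
        assert mc.objective.value == pytest.approx(best_val)

    def test_deterministic_for_fixed_seed(self, small_points):
        a = mc_select(small_points, 5, iterations=500, seed=31)
        b = mc_select(small_points, 5, iterations=500, seed=31)
        assert a == b

    def test_best_so_far_monotone_in_budget(self, small_points):
        budgets = [1, 10, 100, 1000]
        vals = [
            mc_select(small_points, 5, iterations=k, seed=8).objective.value
            for k in budgets
        ]
        assert vals == sorted(vals)

    def test_similar_mode_minimizes(self):
        m = random_point_population(6, 2, seed=23)
        lo = mc_select(m, 3, iterations=5000, seed=1, mode="similar")
        _, best_min = naive_exact(m.values, 3, "similar")
        assert lo.objective.value == pytest.approx(best_min)

    def test_records_seed_and_iterations(self, small_points):
        r = mc_select(small_points, 3, iterations=7, seed=123)
        assert r.seed == 123 and r.iterations == 7

    def test_invalid_iterations(self, small_points):
        with pytest.raises(ValueError, match="iterations"):
            mc_select(small_points, 3, iterations=0, seed=0)


class TestExactSelect:
    def test_n2_matches_initial_pair(self, small_random_matrix):
        L = log_transform(small_random_matrix)
        assert exact_select(small_random_matrix, 2).indices() == select_initial_pair(L)

    def test_full_population_trivial(self, small_points):
        r = exact_select(small_points, small_points.size)
        assert r.indices() == tuple(range(small_points.size))

    @pytest.mark.parametrize("mode", ["dissimilar", "similar"])
    def test_matches_enumeration_oracle(self, mode):
        m = random_matrix(10, seed=6)
        r = exact_select(m, 5, mode=mode)
        best_sub, best_val = naive_exact(m.values, 5, mode)
        assert r.indices() == best_sub
        assert r.objective.value == pytest.approx(best_val)

    def test_beats_every_subset(self):
        import itertools

        m = random_point_population(10, 3, seed=14)
        r = exact_select(m, 5)
        for sub in itertools.combinations(range(10), 5):
            assert r.objective.value >= naive_objective(m.values, sub) - 1e-12

    def test_guard_triggers(self):
        m = random_point_population(40, 2, seed=1)
        with pytest.raises(ValueError, match="guard"):
            exact_select(m, 20, guard=1000)

    def test_guard_override(self):
        m = random_point_population(12, 2, seed=1)
        r = exact_select(m, 6, guard=10, override_guard=True)
        assert len(r.indices()) == 6


class TestCrossMethodProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_sandwich_dissimilar(self, seed):
        m = random_point_population(14, 3, seed=seed)
        n = 7
        exact = exact_select(m, n).objective.value
        sds = sds_select(m, n).objective.value
        mc = mc_select(m, n, iterations=300, seed=seed).objective.value
        minimum = exact_select(m, n, mode="similar").objective.value
        assert exact >= sds >= minimum
        assert mc <= exact

    @pytest.mark.parametrize("seed", range(5))
    def test_sandwich_similar(self, seed):
        m = random_point_population(12, 3, seed=seed + 100)
        n = 5
        exact_min = exact_select(m, n, mode="similar").objective.value
        sds_min = sds_select(m, n, mode="similar").objective.value
        mc_min = mc_select(m, n, iterations=300, seed=seed, mode="similar").objective.value
        assert exact_min <= sds_min
        assert mc_min >= exact_min

    def test_greedy_usually_beats_random_mean(self):
        from downselect.matrix_core import mean_random_objective

        wins = 0
        for seed in range(200):
            m = random_point_population(20, 3, seed=seed)
            if sds_select(m, 10).objective.value > mean_random_objective(m, 10):
                wins += 1
        assert wins >= 190


class TestSelectionResultSerialization:
    def test_summary_round_trips_json(self, small_points):
        import json

        r = sds_select(small_points, 4)
        s = json.loads(json.dumps(r.summary()))
        assert s["method"] == "sds" and s["n"] == 4
        assert s["indices"] == sorted(r.order)
        assert s["order"] == list(r.order)

    def test_report_has_one_line_per_selection(self, small_points):
        r = sds_select(small_points, 5)
        lines = r.report(small_points).strip().splitlines()
        assert len(lines) == 2 + 5  # header + column row + 5 ranks
        assert lines[1].startswith("rank\t")

    def test_mc_summary_records_parameters(self, small_points):
        r = mc_select(small_points, 3, iterations=11, seed=4)
        s = r.summary()
        assert s["iterations"] == 11 and s["seed"] == 4
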