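"""Feasible-set enumeration, dispersion statistics, dominance and rank tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vaxfolio as vf
from vaxfolio.uncertainty import _gini_mean_difference_half

from conftest import constant_pos, make_roster


class TestEnumerateFeasible:
    def test_small_knapsack(self):
        roster = make_roster(["A", "B", "C"], ["RNA"] * 3, [1.0, 2.0, 4.0])
        portfolios = vf.enumerate_feasible(roster, budget=3.0)
        got = {frozenset(p.project_ids(roster)) for p in portfolios}
        assert got == {frozenset({"A"}), frozenset({"B"}), frozenset({"A", "B"})}

    def test_budget_below_minimum_gives_empty(self):
        roster = make_roster(["A"], ["RNA"], [5.0])
        assert vf.enumerate_feasible(roster, budget=4.0) == []

    def test_unconstrained_counts_all_nonempty_subsets(self):
        roster = make_roster(["A", "B", "C", "D"], ["RNA"] * 4, [1.0] * 4)
        assert len(vf.enumerate_feasible(roster, budget=100.0)) == 2**4 - 1

    def test_strict_flag(self):
        roster = make_roster(["A", "B"], ["RNA"] * 2, [2.0, 3.0])
        assert len(vf.enumerate_feasible(roster, budget=5.0)) == 3
        assert len(vf.enumerate_feasible(roster, budget=5.0, strict=True)) == 2

    def test_sorted_by_cost(self, instance):
        portfolios = vf.enumerate_feasible(instance.roster, budget=80.0)
        costs = [p.cost for p in portfolios]
        assert costs == sorted(costs)


class TestDominanceStats:
    def test_constant_draws_have_zero_dispersion(self):
        s = vf.dominance_stats(np.full(100, 0.4))
        for stat in (s.variance, s.semivariance, s.sd, s.mad, s.gini):
            assert stat == pytest.approx(0.0, abs=1e-15)
        assert s.mean_minus_gini == pytest.approx(0.4)

    def test_bernoulli_gini(self):
        # E|X - X'| = 0.5 for a fair {0,1} coin, so Gamma = 0.25
        s = vf.dominance_stats(np.array([0.0, 1.0] * 500))
        assert s.gini == pytest.approx(0.25, abs=1e-12)

    def test_uniform_gini_closed_form(self):
        x = np.random.default_rng(0).random(100_000)
        # E|X - X'| = 1/3 for uniform(0,1)
        assert vf.dominance_stats(x).gini == pytest.approx(1 / 6, abs=0.005)

    def test_fast_identity_matches_naive_double_loop(self):
        x = np.random.default_rng(1).normal(size=2000)
        naive = np.abs(x[:, None] - x[None, :]).sum() / (2 * x.size**2)
        assert abs(_gini_mean_difference_half(x) - naive) < 1e-10

    def test_semivariance_bounded_by_variance(self):
        x = np.random.default_rng(2).normal(size=5000)
        s = vf.dominance_stats(x)
        assert 0 <= s.semivariance <= s.variance

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vf.dominance_stats(np.array([]))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=80))
    def test_gini_identity_property(self, values):
        x = np.array(values)
        naive = np.abs(x[:, None] - x[None, :]).sum() / (2 * x.size**2)
        assert _gini_mean_difference_half(x) == pytest.approx(naive, abs=1e-10)


class TestDominanceRelations:
    def _stats(self, mean, variance):
        return vf.DominanceStats(mean=mean, variance=variance, semivariance=variance / 2,
                                 sd=np.sqrt(variance), mad=np.sqrt(variance) / 2,
                                 gini=np.sqrt(variance) / 3)

    def test_equal_stats_non_comparable(self):
        a = self._stats(1.0, 0.5)
        assert vf.mv_dominates(a, a) == "non-comparable"
        assert vf.mean_gini_dominates(a, a) == "non-comparable"

    def test_higher_mean_lower_variance_dominates(self):
        assert vf.mv_dominates(self._stats(2.0, 0.3), self._stats(1.0, 0.5)) == "dominates"
        assert vf.mv_dominates(self._stats(1.0, 0.5), self._stats(2.0, 0.3)) == "dominated"

    def test_mean_risk_tradeoff_non_comparable(self):
        assert vf.mv_dominates(self._stats(2.0, 0.9), self._stats(1.0, 0.5)) == "non-comparable"

    def test_invalid_risk_measure(self):
        with pytest.raises(ValueError):
            vf.mv_dominates(self._stats(1, 0.1), self._stats(1, 0.1), risk="kurtosis")

    def test_mean_gini_same_mean_smaller_gini_dominates(self):
        a = vf.dominance_stats(np.full(100, 1.0))
        b = vf.dominance_stats(np.array([0.0, 2.0] * 50))
        # both means 1; Gamma 0 vs 0.5: the degenerate distribution dominates
        assert b.gini == pytest.approx(0.5, abs=1e-12)
        assert vf.mean_gini_dominates(a, b) == "dominates"

    def test_mean_optimum_never_mv_dominated(self, instance):
        spec = vf.OptimizationSpec(budget=100.0, objective="expected", seed=1)
        sol = vf.enumerate_optimal(
            instance.roster, instance.pos, instance.pw_draws, instance.levels,
            spec, evaluator=instance.evaluator,
        )
        ref = vf.dominance_stats(instance.evaluator.value_draws_for_mask(sol.portfolio.mask))
        rng = np.random.default_rng(0)
        alternatives = vf.enumerate_feasible(instance.roster, 100.0)
        for p in rng.choice(len(alternatives), size=min(200, len(alternatives)), replace=False):
            other = vf.dominance_stats(
                instance.evaluator.value_draws_for_mask(alternatives[int(p)].mask)
            )
            assert vf.mv_dominates(ref, other) != "dominated"


class TestRankProbability:
    def test_self_comparison_is_half(self, instance):
        p = vf.Portfolio.from_ids(instance.roster, ["P1", "P5"])
        assert vf.rank_probability(
            p, p, instance.pos, instance.pw_draws, instance.levels, instance.roster,
            evaluator=instance.evaluator,
        ) == 0.5

    def test_degenerate_dominant_portfolio(self, levels, table5):
        roster = make_roster(["A", "B"], ["RNA", "RNA"], [1.0, 1.0])
        pos = constant_pos(roster, [0.3, 0.1], n_iter=40)
        draws = vf.PartWorthDraws.point(table5, 40)
        a = vf.Portfolio.from_ids(roster, ["A"])
        b = vf.Portfolio.from_ids(roster, ["B"])
        assert vf.rank_probability(a, b, pos, draws, levels, roster) == 1.0

    def test_symmetry_exact(self, instance):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = vf.Portfolio.from_selection(instance.roster, rng.random(16) < 0.4)
            b = vf.Portfolio.from_selection(instance.roster, rng.random(16) < 0.4)
            pab = vf.rank_probability(a, b, instance.pos, instance.pw_draws,
                                      instance.levels, instance.roster,
                                      evaluator=instance.evaluator)
            pba = vf.rank_probability(b, a, instance.pos, instance.pw_draws,
                                      instance.levels, instance.roster,
                                      evaluator=instance.evaluator)
            assert pab + pba == 1.0

    def test_iteration_mismatch_rejected(self, instance, table5):
        short = vf.PartWorthDraws.point(table5, 10)
        p = vf.Portfolio.from_ids(instance.roster, ["P1"])
        with pytest.raises(ValueError, match="[Ii]teration"):
            vf.rank_probability(p, p, instance.pos, short, instance.levels, instance.roster)


class TestOutrankingReport:
    def test_identical_single_alternative(self, instance):
        p = vf.Portfolio.from_ids(instance.roster, ["P1", "P9"])
        report = vf.outranking_report(
            p, [p], instance.pos, instance.pw_draws, instance.levels, instance.roster,
            evaluator=instance.evaluator,
        )
        assert report.table["outranking_probability"].iloc[0] == 0.5
        row = report.inclusion.iloc[0]
        assert row["P1"] == 1.0 and row["P9"] == 1.0 and row["P2"] == 0.0

    def test_strictly_dominated_point_masses(self, levels, table5):
        roster = make_roster(["A", "B", "C"], ["RNA"] * 3, [1.0] * 3)
        pos = constant_pos(roster, [0.5, 0.1, 0.05], n_iter=30)
        draws = vf.PartWorthDraws.point(table5, 30)
        ref = vf.Portfolio.from_ids(roster, ["A"])
        alts = [vf.Portfolio.from_ids(roster, ["B"]), vf.Portfolio.from_ids(roster, ["C"])]
        report = vf.outranking_report(ref, alts, pos, draws, levels, roster)
        assert np.all(report.table["outranking_probability"] == 1.0)

    def test_empty_alternatives_rejected(self, instance):
        p = vf.Portfolio.from_ids(instance.roster, ["P1"])
        with pytest.raises(ValueError, match="non-empty"):
            vf.outranking_report(
                p, [], instance.pos, instance.pw_draws, instance.levels, instance.roster,
                evaluator=instance.evaluator,
            )

    def test_composition_delta(self, instance):
        ref = vf.Portfolio.from_ids(instance.roster, ["P1", "P2"])
        alt = vf.Portfolio.from_ids(instance.roster, ["P1", "P3"])
        report = vf.outranking_report(
            ref, [alt], instance.pos, instance.pw_draws, instance.levels, instance.roster,
            evaluator=instance.evaluator,
        )
        assert report.table["added"].iloc[0] == "P3"
        assert report.table["removed"].iloc[0] == "P2"
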