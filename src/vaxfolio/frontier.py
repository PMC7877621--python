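"""Efficiency frontier, PoS-to-cost comparator and platform value curves.

The efficiency frontier traces the best attainable portfolio objective as
the budget grows from the cheapest single project to the full roster cost.
The PoS-to-cost comparator reproduces the naive ranking heuristic the
optimization is compared against: rank projects by expected PoS per US$
million and greedily add affordable ones. Platform value curves show, for a
single platform type, how POS>=1 and portfolio value grow as projects are
added one at a time — the decreasing returns induced by the piecewise
preference function.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .optimize import (
    OptimizationSpec,
    Solution,
    _mask_costs,
    _tie_break,
    evolve_optimal,
    feasible_masks,
)
from .pos import ProjectPoSDraws
from .preference import AttributeLevels, PartWorthDraws, value_contribution
from .roster import Portfolio, ProjectRoster
from .value import PortfolioEvaluator, value_summary

__all__ = ["FrontierPoint", "build_frontier", "frontier_frame", "pos_to_cost_ranking", "platform_value_curve"]


@dataclass(frozen=True, eq=False)
class FrontierPoint:
    """Optimal solution at one budget grid value."""

    budget: float
    portfolio: Portfolio
    objective: float
    mean: float
    ci_low: float
    ci_high: float


def build_frontier(
    roster: ProjectRoster,
    pos: ProjectPoSDraws,
    pw_draws: PartWorthDraws,
    levels: AttributeLevels,
    budgets: Sequence[float] | None = None,
    spec: OptimizationSpec | None = None,
    evaluator: PortfolioEvaluator | None = None,
) -> list[FrontierPoint]:
    """Optimal solutions along a budget grid under fixed common draws.

    With the enumerating solver and no explicit grid, the exact frontier is
    returned: one point per budget breakpoint at which the optimum improves,
    from the cheapest project to the total roster cost. An explicit grid
    must be strictly increasing.
    """
    if spec is None:
        spec = OptimizationSpec()
    if budgets is not None:
        budgets = [float(b) for b in budgets]
        if len(budgets) == 0:
            raise ValueError("budget grid must be non-empty")
        if any(b2 <= b1 for b1, b2 in zip(budgets, budgets[1:])):
            raise ValueError("budget grid must be strictly increasing")

    if spec.solver == "evolve":
        if budgets is None:
            budgets = list(
                np.linspace(float(roster.budgets.min()), roster.total_budget, 20)
            )
        points = []
        for b in budgets:
            sol = evolve_optimal(roster, pos, pw_draws, levels, replace(spec, budget=b),
                                 evaluator=evaluator)
            points.append(
                FrontierPoint(
                    budget=b,
                    portfolio=sol.portfolio,
                    objective=sol.objective,
                    mean=sol.summary.mean,
                    ci_low=sol.summary.ci_low,
                    ci_high=sol.summary.ci_high,
                )
            )
        return points

    if evaluator is None:
        evaluator = PortfolioEvaluator(roster, pos, pw_draws, levels)
    max_budget = budgets[-1] if budgets is not None else roster.total_budget
    masks = feasible_masks(roster, max_budget)
    costs = _mask_costs(roster.budgets, roster.n_projects)[masks]
    objectives = evaluator.objective_values(masks, spec.objective, spec.q)
    order = np.argsort(costs, kind="stable")

    points: list[FrontierPoint] = []

    def emit(budget: float, mask: int, objective: float) -> None:
        draws = evaluator.value_draws_for_mask(mask)
        s = value_summary(draws)
        points.append(
            FrontierPoint(
                budget=budget,
                portfolio=Portfolio.from_mask(roster, mask),
                objective=objective,
                mean=s.mean,
                ci_low=s.ci_low,
                ci_high=s.ci_high,
            )
        )

    if budgets is None:
        best = -np.inf
        best_mask = 0
        for j in order:
            if objectives[j] > best:
                best = float(objectives[j])
                best_mask = int(masks[j])
                if best_mask != 0:
                    emit(costs[j], best_mask, best)
        return points

    sorted_costs = costs[order]
    sorted_obj = objectives[order]
    sorted_masks = masks[order]
    running = np.maximum.accumulate(sorted_obj)
    for b in budgets:
        upto = int(np.searchsorted(sorted_costs, b, side="right"))
        if upto == 0:
            emit(b, 0, float(evaluator.objective_values(np.array([0]), spec.objective, spec.q)[0]))
            continue
        sub_masks = sorted_masks[:upto]
        sub_obj = sorted_obj[:upto]
        best_mask = _tie_break(sub_masks, sub_obj, roster)
        emit(b, best_mask, float(sub_obj.max()))
    return points


def frontier_frame(points: Sequence[FrontierPoint], roster: ProjectRoster) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "budget_musd": [p.budget for p in points],
            "project_ids": ["+".join(p.portfolio.project_ids(roster)) for p in points],
            "cost_musd": [p.portfolio.cost for p in points],
            "objective": [p.objective for p in points],
            "mean": [p.mean for p in points],
            "ci_low": [p.ci_low for p in points],
            "ci_high": [p.ci_high for p in points],
        }
    )


def pos_to_cost_ranking(
    roster: ProjectRoster, pos: ProjectPoSDraws, budget: float
) -> Portfolio:
    """Greedy comparator: rank by mean PoS per US$ million, add affordable.

    Projects are added in rank order; a project that would exceed the budget
    is skipped and the scan continues down the list.
    """
    means = pos.samples.mean(axis=0)
    ratio = means / roster.budgets
    order = np.argsort(-ratio, kind="stable")
    selection = np.zeros(roster.n_projects, dtype=bool)
    spent = 0.0
    for i in order:
        if spent + roster.budgets[i] <= budget:
            selection[i] = True
            spent += float(roster.budgets[i])
    return Portfolio.from_selection(roster, selection, label="pos-to-cost")


def platform_value_curve(
    roster: ProjectRoster,
    pos: ProjectPoSDraws,
    pw_draws: PartWorthDraws,
    levels: AttributeLevels,
    platform: str,
) -> pd.DataFrame:
    """Best m-subset value per subset size for a single platform type.

    For m = 1 .. s_k, the member subset of size m with the highest mean
    value contribution is reported with its mean POS>=1 and mean value.
    """
    idx = roster.members(platform)  # raises on unknown platform
    a, b, c = levels[platform]
    s = idx.size
    rows = []
    best_by_size: dict[int, tuple[float, float, tuple[str, ...]]] = {}
    for pattern in range(1, 1 << s):
        members = [int(idx[j]) for j in range(s) if (pattern >> j) & 1]
        p_draws = 1.0 - np.prod(1.0 - pos.samples[:, members], axis=1)
        contrib = value_contribution(
            pw_draws.beta_b[platform], pw_draws.beta_c[platform], (a, b, c), p_draws
        )
        m = len(members)
        entry = (
            float(contrib.mean()),
            float(p_draws.mean()),
            tuple(roster.ids[i] for i in members),
        )
        if m not in best_by_size or entry[0] > best_by_size[m][0]:
            best_by_size[m] = entry
    for m in sorted(best_by_size):
        value_mean, pos_mean, ids = best_by_size[m]
        rows.append(
            {
                "platform": platform,
                "n_projects": m,
                "project_ids": "+".join(ids),
                "pos_ge1_mean": pos_mean,
                "value_mean": value_mean,
            }
        )
    return pd.DataFrame(rows)
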