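"""Chance-constrained binary portfolio selection.

The selection problem maximizes the simulated portfolio value V_p subject to
a budget constraint on the summed project costs,

    max_x  objective( V_p(x) )   s.t.  sum_i B_i x_i <= B,  x_i in {0, 1},

where the objective is either the Monte Carlo mean of V_p or, to express the
chance constraint, an empirical quantile of V_p (value-at-risk style; level
q = 0.95 by default, with the 0.50-0.90 range available for comparison
runs). Two solvers are provided: exhaustive enumeration of all feasible
subsets (exact, used as the oracle for rosters up to 24 projects) and a
genetic algorithm (scalable path). Both evaluate candidates on the same
cached common-random-number draws, so their objectives are directly
comparable and the genetic solver can never exceed the enumerated optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._rng import substream
from .pos import ProjectPoSDraws
from .preference import AttributeLevels, PartWorthDraws
from .roster import Portfolio, ProjectRoster
from .value import PortfolioEvaluator, ValueSummary, empirical_quantile, value_summary

__all__ = [
    "GASettings",
    "OptimizationSpec",
    "Solution",
    "enumerate_optimal",
    "evolve_optimal",
    "objective_value",
    "feasible_masks",
]

ENUMERATION_GUARD = 24


@dataclass(frozen=True)
class GASettings:
    """Genetic-algorithm hyperparameters (binary chromosome)."""

    population: int = 96
    generations: int = 150
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # default 1/n_projects
    tournament: int = 3
    patience: int = 30
    elitism: int = 1


@dataclass(frozen=True)
class OptimizationSpec:
    """Budget, objective and solver settings for the selection problem."""

    budget: float = 140.0
    objective: str = "quantile"  # "expected" | "quantile"
    q: float = 0.95
    n_iterations: int = 10_000
    seed: int = 0
    solver: str = "enumerate"  # "enumerate" | "evolve"
    ga: GASettings = field(default_factory=GASettings)

    def __post_init__(self) -> None:
        if self.budget <= 0:
            raise ValueError("budget must be positive")
        if not 0.0 < self.q < 1.0:
            raise ValueError("quantile level q must lie in (0, 1)")
        if self.objective not in ("expected", "quantile"):
            raise ValueError("objective must be 'expected' or 'quantile'")


@dataclass(frozen=True, eq=False)
class Solution:
    """An optimizer result: the portfolio, its objective and value summary."""

    portfolio: Portfolio
    objective: float
    summary: ValueSummary
    trace: dict


def objective_value(samples: np.ndarray, spec: OptimizationSpec) -> float:
    """The scalar objective of a draw vector under ``spec``."""
    samples = np.asarray(samples, dtype=float).ravel()
    if spec.objective == "expected":
        return float(samples.mean())
    return empirical_quantile(samples, spec.q)


def _mask_costs(budgets: np.ndarray, n: int) -> np.ndarray:
    """Cost of every subset mask 0 .. 2^n - 1, computed chunk-wise."""
    total = 1 << n
    costs = np.empty(total)
    chunk = 1 << 16
    bit_idx = np.arange(n)
    for start in range(0, total, chunk):
        stop = min(start + chunk, total)
        masks = np.arange(start, stop, dtype=np.int64)
        bits = (masks[:, None] >> bit_idx) & 1
        costs[start:stop] = bits @ budgets
    return costs


def feasible_masks(roster: ProjectRoster, budget: float, strict: bool = False) -> np.ndarray:
    """All subset masks (including the empty set) within the budget."""
    n = roster.n_projects
    if n > ENUMERATION_GUARD:
        raise ValueError(
            f"roster of {n} projects exceeds the enumeration guard of "
            f"{ENUMERATION_GUARD}; use the genetic solver"
        )
    costs = _mask_costs(roster.budgets, n)
    keep = costs < budget if strict else costs <= budget
    return np.nonzero(keep)[0].astype(np.int64)


def _tie_break(
    masks: Sequence[int], objectives: np.ndarray, roster: ProjectRoster
) -> int:
    """Argmax mask; ties go to lower cost, then lexicographically smallest selection."""
    best = objectives.max()
    candidates = [int(m) for m, o in zip(masks, objectives) if o == best]
    def key(mask: int):
        sel = tuple((mask >> i) & 1 for i in range(roster.n_projects))
        return (float(roster.budgets[np.array(sel, dtype=bool)].sum()), sel)
    return min(candidates, key=key)


def enumerate_optimal(
    roster: ProjectRoster,
    pos: ProjectPoSDraws,
    pw_draws: PartWorthDraws,
    levels: AttributeLevels,
    spec: OptimizationSpec,
    evaluator: PortfolioEvaluator | None = None,
) -> Solution:
    """Exact solution by evaluating every feasible subset."""
    if roster.n_projects > ENUMERATION_GUARD:
        raise ValueError(
            f"roster of {roster.n_projects} projects exceeds the enumeration "
            f"guard of {ENUMERATION_GUARD}; use the genetic solver"
        )
    if evaluator is None:
        evaluator = PortfolioEvaluator(roster, pos, pw_draws, levels)
    masks = feasible_masks(roster, spec.budget)
    objectives = evaluator.objective_values(masks, spec.objective, spec.q)
    best_mask = _tie_break(masks, objectives, roster)
    portfolio = Portfolio.from_mask(roster, best_mask, label="enumerated-optimum")
    draws = evaluator.value_draws_for_mask(best_mask)
    return Solution(
        portfolio=portfolio,
        objective=float(objectives.max()),
        summary=value_summary(draws),
        trace={"solver": "enumerate", "evaluations": int(masks.size)},
    )


def evolve_optimal(
    roster: ProjectRoster,
    pos: ProjectPoSDraws,
    pw_draws: PartWorthDraws,
    levels: AttributeLevels,
    spec: OptimizationSpec,
    evaluator: PortfolioEvaluator | None = None,
) -> Solution:
    """Genetic-algorithm solution: tournament selection, uniform crossover,
    per-bit mutation, elitism, and a death penalty on infeasible chromosomes.

    Deterministic given the spec seed. When no feasible non-empty chromosome
    is ever found the empty portfolio is returned (its value is zero).
    """
    if evaluator is None:
        evaluator = PortfolioEvaluator(roster, pos, pw_draws, levels)
    n = roster.n_projects
    ga = spec.ga
    mutation = ga.mutation_rate if ga.mutation_rate is not None else 1.0 / n
    rng = substream(spec.seed, "ga")
    cache: dict[int, float] = {}

    def fitness(mask: int) -> float:
        if mask not in cache:
            cost = float(roster.budgets[
                np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
            ].sum())
            if cost > spec.budget:
                cache[mask] = -np.inf
            else:
                cache[mask] = float(
                    evaluator.objective_values(np.array([mask]), spec.objective, spec.q)[0]
                )
        return cache[mask]

    pop = rng.random((ga.population, n)) < 0.5
    masks = [int(sum(1 << i for i in range(n) if row[i])) for row in pop]
    fits = np.array([fitness(m) for m in masks])
    best_mask = 0
    best_fit = fitness(0)
    converged_at = 0
    stall = 0
    gen = 0
    for gen in range(1, ga.generations + 1):
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = masks[gen_best]
            converged_at = gen
            stall = 0
        else:
            stall += 1
        if stall > ga.patience:
            break
        new_masks: list[int] = []
        if ga.elitism and np.isfinite(fits).any():
            order = np.argsort(fits)[::-1]
            for j in order[: ga.elitism]:
                new_masks.append(masks[int(j)])
        while len(new_masks) < ga.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, ga.population, ga.tournament)
                winner = contenders[np.argmax(fits[contenders])]
                parents.append(masks[int(winner)])
            if rng.random() < ga.crossover_rate:
                template = int(rng.integers(0, 1 << n))
                child = (parents[0] & template) | (parents[1] & ~template)
            else:
                child = parents[0]
            flip = rng.random(n) < mutation
            for i in np.nonzero(flip)[0]:
                child ^= 1 << int(i)
            new_masks.append(child)
        masks = new_masks
        fits = np.array([fitness(m) for m in masks])

    if best_mask == 0 and spec.budget < float(roster.budgets.min()):
        warnings.warn(
            "budget below the cheapest project: no feasible non-empty portfolio",
            stacklevel=2,
        )
    portfolio = Portfolio.from_mask(roster, best_mask, label="ga-optimum")
    draws = evaluator.value_draws_for_mask(best_mask)
    trace = {
        "solver": "evolve",
        "evaluations": len(cache),
        "generations_run": gen,
        "improved_last_at_generation": converged_at,
        "feasible_found": bool(np.isfinite(best_fit)),
    }
    return Solution(
        portfolio=portfolio,
        objective=float(best_fit),
        summary=value_summary(draws),
        trace=trace,
    )
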