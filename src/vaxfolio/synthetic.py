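"""Synthetic elicitation data with the structure the analysis assumes.

The study's reviewer assessments and survey responses are confidential, so
this module generates stand-ins carrying the same statistical structure: a
roster of platform projects with budgets; a balanced reviewer assignment
(a pool of reviewers, each project scored by a few of them, each reviewer
covering a few projects); three-point triangular factor assessments, with an
optional optimism shift that shrinks the "final" assessments toward zero
relative to the "initial" ones; and choice-survey responses drawn from a
conditional logit with known true part-worths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import substream
from .pos import FACTORS, ASSESSMENT_COLUMNS, AssessmentTable
from .preference import (
    ChoiceData,
    ChoiceDesign,
    PartWorths,
    default_part_worths,
    design_matrix,
    slug,
)
from .roster import PLATFORMS, ProjectRoster

__all__ = [
    "FactorPrior",
    "DCEConfig",
    "SyntheticConfig",
    "AssignmentMap",
    "generate_roster",
    "assign_reviewers",
    "generate_assessments",
    "generate_choice_responses",
]


@dataclass(frozen=True)
class FactorPrior:
    """Prior for a reviewer's (worst, most-likely, best) triple on a factor.

    The most-likely value is a Beta(mode_alpha, mode_beta) draw (or the fixed
    point ``fixed_mode`` when set); worst/best are a symmetric half-width
    drawn uniformly from ``spread`` below/above the mode, clipped to [0, 1].
    """

    mode_alpha: float = 8.0
    mode_beta: float = 2.0
    fixed_mode: float | None = None
    spread: tuple[float, float] = (0.05, 0.30)

    def sample(self, rng: np.random.Generator, size: int):
        if self.fixed_mode is not None:
            mode = np.full(size, float(self.fixed_mode))
        else:
            mode = rng.beta(self.mode_alpha, self.mode_beta, size=size)
        half = rng.uniform(self.spread[0], self.spread[1], size=size)
        worst = np.clip(mode - half, 0.0, 1.0)
        best = np.clip(mode + half, 0.0, 1.0)
        return worst, mode, best


@dataclass(frozen=True)
class DCEConfig:
    """Choice-survey dimensions and the data-generating part-worths."""

    participants: int = 48
    blocks: int = 2
    sets_per_block: int = 16
    alternatives_per_set: int = 3
    true_part_worths: PartWorths = field(default_factory=default_part_worths)


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic elicitation study.

    Defaults mirror the study conditions: 16 projects in platform groups of
    4/4/3/3/2, budgets on US$ 6-65 million, a pool of 27 reviewers with 4-5
    reviewers per project and 3-4 projects per reviewer, and a 48-participant
    survey of 2 blocks x 16 choice sets of 3 alternatives.
    """

    seed: int = 0
    n_projects: int = 16
    platform_sizes: tuple[int, ...] = (4, 4, 3, 3, 2)
    budget_range: tuple[float, float] = (6.0, 65.0)
    n_reviewers_pool: int = 27
    reviewers_per_project: tuple[int, int] = (4, 5)
    projects_per_reviewer: tuple[int, int] = (3, 4)
    factor_prior: FactorPrior | Mapping[str, FactorPrior] = field(default_factory=FactorPrior)
    optimism_shift: float = 0.2
    dce: DCEConfig = field(default_factory=DCEConfig)

    def __post_init__(self) -> None:
        if sum(self.platform_sizes) != self.n_projects:
            raise ValueError(
                f"platform_sizes sum to {sum(self.platform_sizes)}, expected {self.n_projects}"
            )
        if self.budget_range[0] <= 0 or self.budget_range[1] < self.budget_range[0]:
            raise ValueError("budget_range must be positive with lower <= upper")
        if not 0.0 <= self.optimism_shift < 1.0:
            raise ValueError("optimism_shift must lie in [0, 1)")
        for name, pair in (
            ("reviewers_per_project", self.reviewers_per_project),
            ("projects_per_reviewer", self.projects_per_reviewer),
        ):
            if pair[0] < 1 or pair[1] < pair[0]:
                raise ValueError(f"{name} must be a positive (min, max) range")
        if self.n_reviewers_pool < 1 or self.n_projects < 1:
            raise ValueError("counts must be positive")

    def prior_for(self, factor: str) -> FactorPrior:
        if isinstance(self.factor_prior, FactorPrior):
            return self.factor_prior
        return self.factor_prior[factor]


@dataclass(frozen=True)
class AssignmentMap:
    """Reviewer ids per project."""

    by_project: Mapping[str, tuple[str, ...]]

    def loads(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for reviewers in self.by_project.values():
            for r in reviewers:
                out[r] = out.get(r, 0) + 1
        return out

    def get(self, project_id, default=()):
        return self.by_project.get(project_id, default)

    def __getitem__(self, project_id: str):
        return self.by_project[project_id]


def generate_roster(config: SyntheticConfig) -> ProjectRoster:
    """Draw a project roster: sequential ids, grouped platforms, uniform budgets.

    Budgets are uniform on ``budget_range`` rounded to US$ 0.1 million.
    """
    rng = substream(config.seed, "roster")
    platform_types: list[str] = []
    for size, platform in zip(config.platform_sizes, PLATFORMS):
        platform_types.extend([platform] * size)
    budgets = np.round(
        rng.uniform(config.budget_range[0], config.budget_range[1], config.n_projects), 1
    )
    # rounding must not escape the configured range
    budgets = np.clip(budgets, config.budget_range[0], config.budget_range[1])
    ids = tuple(f"P{i + 1}" for i in range(config.n_projects))
    return ProjectRoster(ids=ids, platform_types=tuple(platform_types), budgets=budgets)


def assign_reviewers(config: SyntheticConfig, roster: ProjectRoster) -> AssignmentMap:
    """Randomized balanced assignment of pool reviewers to projects.

    Every project receives between min and max reviewers; every *assigned*
    reviewer covers between min and max projects (the pool may be larger
    than the number of reviewers actually needed).
    """
    min_r, max_r = config.reviewers_per_project
    min_l, max_l = config.projects_per_reviewer
    pool = config.n_reviewers_pool
    if min_r > pool:
        raise ValueError(
            f"infeasible assignment: each project needs >= {min_r} distinct reviewers "
            f"but the pool has only {pool}"
        )
    if roster.n_projects * min_r > pool * max_l:
        raise ValueError(
            "infeasible assignment: total reviewer capacity "
            f"({pool} reviewers x {max_l} projects) cannot cover "
            f"{roster.n_projects} projects x {min_r} reviewers"
        )
    rng = substream(config.seed, "assignment")
    reviewer_ids = [f"R{j + 1:02d}" for j in range(pool)]
    for _attempt in range(50):
        need = rng.integers(min_r, max_r + 1, size=roster.n_projects)
        total = int(need.sum())
        m_lo = max(math.ceil(total / max_l), int(need.max()))
        m_hi = min(pool, total // min_l)
        if m_lo > m_hi:
            continue
        m = int(rng.integers(m_lo, m_hi + 1))
        used = list(rng.choice(pool, size=m, replace=False))
        capacity = np.full(m, min_l)
        extra = total - m * min_l
        room = np.full(m, max_l - min_l)
        while extra > 0:
            candidates = np.nonzero(room > 0)[0]
            pick = int(rng.choice(candidates))
            capacity[pick] += 1
            room[pick] -= 1
            extra -= 1
        remaining = capacity.astype(float).copy()
        assignment: dict[str, tuple[str, ...]] = {}
        ok = True
        order = rng.permutation(roster.n_projects)
        for j in order:
            r_p = int(need[j])
            if np.count_nonzero(remaining > 0) < r_p:
                ok = False
                break
            noise = rng.random(m)
            ranked = np.lexsort((noise, -remaining))
            chosen = ranked[:r_p]
            remaining[chosen] -= 1
            assignment[roster.ids[j]] = tuple(
                sorted(reviewer_ids[used[c]] for c in chosen)
            )
        if ok:
            ordered = {pid: assignment[pid] for pid in roster.ids}
            return AssignmentMap(by_project=ordered)
    raise ValueError("infeasible assignment: could not satisfy per-reviewer load range")


def generate_assessments(
    config: SyntheticConfig, assignment: AssignmentMap
) -> dict[str, AssessmentTable]:
    """Three-point factor assessments for every reviewer-project pair.

    Returns ``{"initial": ..., "final": ...}``; the final table is the
    initial one with all three triple points shrunk multiplicatively by
    ``(1 - optimism_shift)``, emulating the lower post-deliberation
    estimates. With a zero shift the two stages are identical.
    """
    rng = substream(config.seed, "assessments")
    rows = []
    for pid, reviewers in assignment.by_project.items():
        for rid in reviewers:
            for factor in FACTORS:
                worst, mode, best = config.prior_for(factor).sample(rng, 1)
                rows.append(
                    {
                        "reviewer_id": rid,
                        "project_id": pid,
                        "factor": factor,
                        "worst": float(worst[0]),
                        "most_likely": float(mode[0]),
                        "best": float(best[0]),
                        "stage": "initial",
                    }
                )
    initial = pd.DataFrame(rows, columns=list(ASSESSMENT_COLUMNS))
    shrink = 1.0 - config.optimism_shift
    final = initial.copy()
    final[["worst", "most_likely", "best"]] *= shrink
    final["stage"] = "final"
    return {
        "initial": AssessmentTable(initial),
        "final": AssessmentTable(final),
    }


def generate_choice_responses(
    config: SyntheticConfig,
    design: ChoiceDesign,
    truth: PartWorths,
    rng: np.random.Generator | None = None,
) -> ChoiceData:
    """Simulate survey responses from a conditional logit with known truth.

    Each participant answers one block; within each choice set the chosen
    alternative is drawn with probability proportional to exp(U_j).
    """
    missing = [p for p in design.platforms if p not in truth.platforms]
    if missing:
        raise ValueError(f"true part-worths missing platforms {missing}")
    if rng is None:
        rng = substream(config.seed, "choices")
    beta = []
    for p in design.platforms:
        beta.extend([truth.beta_b[p], truth.beta_c[p]])
    beta = np.array(beta)

    n_sets = design.sets_per_block
    alts = design.n_alternatives
    probs_by_block = []
    for b in range(design.n_blocks):
        stacked = np.vstack(design.sets[b])  # (n_sets*alts, n_platforms)
        eta = (design_matrix(stacked, design.platforms, design.levels) @ beta).reshape(
            n_sets, alts
        )
        e = np.exp(eta - eta.max(axis=1, keepdims=True))
        probs_by_block.append(e / e.sum(axis=1, keepdims=True))

    n_participants = config.dce.participants
    blocks = np.arange(n_participants) % design.n_blocks
    # draw choices participant-by-participant so the stream order is stable
    chosen = np.empty((n_participants, n_sets), dtype=int)
    for p in range(n_participants):
        probs = probs_by_block[blocks[p]]
        u = rng.random(n_sets)
        chosen[p] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)

    frames = []
    rows_per_block = n_sets * alts
    for b in range(design.n_blocks):
        members = np.nonzero(blocks == b)[0]
        if members.size == 0:
            continue
        stacked = np.vstack(design.sets[b])
        set_ids = np.repeat([design.set_id(b, s) for s in range(n_sets)], alts)
        alt_ids = np.tile(np.arange(1, alts + 1), n_sets)
        frame = pd.DataFrame(
            {
                "participant_id": np.repeat(
                    [f"S{p + 1:03d}" for p in members], rows_per_block
                ),
                "block": b + 1,
                "set_id": np.tile(set_ids, members.size),
                "alternative_id": np.tile(alt_ids, members.size),
            }
        )
        for kk, platform in enumerate(design.platforms):
            frame[f"level_{slug(platform)}"] = np.tile(stacked[:, kk], members.size)
        frame["chosen"] = (
            frame["alternative_id"].to_numpy()
            == np.repeat(chosen[members] + 1, alts).ravel()
        ).astype(int)
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    data = data.sort_values(
        ["participant_id", "set_id", "alternative_id"], kind="stable"
    ).reset_index(drop=True)
    return ChoiceData(data, design.platforms)
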