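"""Shared fixtures: a seeded synthetic study instance and small toy objects."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import vaxfolio as vf
from vaxfolio._rng import substream

SEED = 7
N_ITER = 2000


def make_roster(ids, platforms, budgets) -> vf.ProjectRoster:
    return vf.ProjectRoster(
        ids=tuple(ids), platform_types=tuple(platforms), budgets=np.array(budgets, float)
    )


def constant_pos(roster: vf.ProjectRoster, values, n_iter: int = 100) -> vf.ProjectPoSDraws:
    """Point-mass PoS draws: each project's PoS fixed at its given value."""
    values = np.asarray(
        [values[pid] for pid in roster.ids] if isinstance(values, dict) else values,
        dtype=float,
    )
    return vf.ProjectPoSDraws(
        samples=np.tile(values, (n_iter, 1)), project_ids=roster.ids
    )


def point_assessments(
    roster: vf.ProjectRoster, factor_value: float, reviewers=("R1",)
) -> vf.AssessmentTable:
    rows = []
    for pid in roster.ids:
        for rid in reviewers:
            for f in vf.FACTORS:
                rows.append(
                    {
                        "reviewer_id": rid,
                        "project_id": pid,
                        "factor": f,
                        "worst": factor_value,
                        "most_likely": factor_value,
                        "best": factor_value,
                        "stage": "initial",
                    }
                )
    return vf.AssessmentTable(pd.DataFrame(rows))


@dataclass
class StudyInstance:
    """One fully simulated synthetic study at a fixed seed."""

    config: vf.SyntheticConfig
    roster: vf.ProjectRoster
    assignment: vf.AssignmentMap
    tables: dict
    pos: vf.ProjectPoSDraws
    pw: vf.PartWorths
    pw_draws: vf.PartWorthDraws
    levels: vf.AttributeLevels
    evaluator: vf.PortfolioEvaluator


def build_instance(seed: int, n_iter: int = N_ITER) -> StudyInstance:
    config = vf.SyntheticConfig(seed=seed)
    roster = vf.generate_roster(config)
    assignment = vf.assign_reviewers(config, roster)
    tables = vf.generate_assessments(config, assignment)
    pos = vf.simulate_project_pos(
        tables["final"], assignment, roster, n_iter=n_iter, rng=substream(seed, "pos")
    )
    pw = vf.default_part_worths()
    pw_draws = vf.sample_part_worths(pw, n_iter, substream(seed, "part-worths"))
    levels = vf.default_attribute_levels()
    evaluator = vf.PortfolioEvaluator(roster, pos, pw_draws, levels)
    return StudyInstance(
        config=config,
        roster=roster,
        assignment=assignment,
        tables=tables,
        pos=pos,
        pw=pw,
        pw_draws=pw_draws,
        levels=levels,
        evaluator=evaluator,
    )


@pytest.fixture(scope="session")
def instance() -> StudyInstance:
    return build_instance(SEED)


@pytest.fixture(scope="session")
def levels() -> vf.AttributeLevels:
    return vf.default_attribute_levels()


@pytest.fixture(scope="session")
def table5() -> vf.PartWorths:
    return vf.default_part_worths()
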