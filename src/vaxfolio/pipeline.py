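"""End-to-end pipeline, file I/O and reproducibility manifest.

The full analysis runs in stages: data (loaded or synthetic) -> project-PoS
simulation -> preference fit or published fixture -> valuation -> budget
optimization -> efficiency frontier -> uncertainty/rank analysis. Every
numeric output is a deterministic function of the master seed and the
inputs, recorded in a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import substream
from .frontier import build_frontier, frontier_frame, pos_to_cost_ranking, platform_value_curve
from .optimize import GASettings, OptimizationSpec, enumerate_optimal, evolve_optimal
from .pos import AssessmentTable, simulate_project_pos
from .preference import (
    AttributeLevels,
    ChoiceData,
    PartWorths,
    build_design,
    default_attribute_levels,
    default_part_worths,
    fit_conditional_logit,
    sample_part_worths,
    validity_checks,
)
from .roster import Portfolio, ProjectRoster
from .synthetic import (
    SyntheticConfig,
    assign_reviewers,
    generate_assessments,
    generate_choice_responses,
    generate_roster,
)
from .uncertainty import dominance_stats, enumerate_feasible, outranking_report
from .value import PortfolioEvaluator, value_summary

__all__ = [
    "RunConfig",
    "RunManifest",
    "run_pipeline",
    "read_roster_xlsx",
    "reference_roster",
]

# Synthetic stand-in for the study's (confidential) project budgets. The
# platform grouping of P1..P16 is the published one; the individual budgets
# are synthetic values constructed to match the published summary statistics
# only: range US$ 6-65 million, median 22, total 390.
_REFERENCE_ROSTER = (
    ("P1", "Protein", 23.0),
    ("P2", "RNA", 35.0),
    ("P3", "DNA", 10.0),
    ("P4", "Viral Vector", 38.0),
    ("P5", "mAb", 6.0),
    ("P6", "mAb", 8.0),
    ("P7", "RNA", 29.0),
    ("P8", "DNA", 14.0),
    ("P9", "Protein", 19.0),
    ("P10", "Viral Vector", 21.0),
    ("P11", "RNA", 33.0),
    ("P12", "Viral Vector", 26.0),
    ("P13", "Viral Vector", 16.0),
    ("P14", "Protein", 12.0),
    ("P15", "DNA", 35.0),
    ("P16", "RNA", 65.0),
)


def reference_roster() -> ProjectRoster:
    """The synthetic 16-project reference roster (published platform grouping,
    synthetic budgets matching the published range/median/total)."""
    ids, platforms, budgets = zip(*_REFERENCE_ROSTER)
    return ProjectRoster(ids=ids, platform_types=platforms, budgets=np.array(budgets))


def read_roster_xlsx(
    path: str | Path,
    sheet: int | str = 0,
    column_map: Mapping[str, str] | None = None,
) -> ProjectRoster:
    """Load a roster from a spreadsheet.

    ``column_map`` maps source column names to the expected
    ``project_id / platform_type / budget_musd``; without it the sheet must
    already carry those names.
    """
    frame = pd.read_excel(path, sheet_name=sheet)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    try:
        return ProjectRoster.from_frame(frame)
    except ValueError as exc:
        raise ValueError(
            f"{exc}; pass column_map to map your sheet's columns onto "
            "project_id / platform_type / budget_musd"
        ) from exc


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    seed: int
    out_dir: str
    roster_path: str | None = None
    use_reference_roster: bool = False
    assessments_path: str | None = None
    choices_path: str | None = None
    part_worths_path: str | None = None
    fit_dce: bool = False  # fit synthetic DCE responses instead of the published fixture
    stage: str = "final"  # which assessment stage feeds the optimization
    budget: float = 140.0
    objective: str = "quantile"
    q: float = 0.95
    n_iterations: int = 10_000
    solver: str = "enumerate"
    synthetic: SyntheticConfig | None = None

    def __post_init__(self) -> None:
        sources = sum(
            [self.roster_path is not None, self.use_reference_roster, self.synthetic is not None]
        )
        if sources == 0:
            raise ValueError(
                "no roster source: set roster_path, use_reference_roster or a synthetic config"
            )
        if self.roster_path is not None and self.use_reference_roster:
            raise ValueError("set only one roster source")
        if self.stage not in ("initial", "final"):
            raise ValueError("stage must be 'initial' or 'final'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        syn = payload.pop("synthetic", None)
        if syn is not None:
            syn = SyntheticConfig(**syn)
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(synthetic=syn, **payload)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run's numeric outputs."""

    tool_version: str
    seed: int
    config_hash: str
    input_hashes: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    notes: dict = field(default_factory=dict)
    timestamp: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _hash_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage and write stage outputs plus the manifest.

    On a stage failure a FAILED marker naming the stage is left in the
    output directory and the error re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        tool_version=__version__,
        seed=config.seed,
        config_hash=_config_hash(config),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    syn = config.synthetic or SyntheticConfig(seed=config.seed)
    stage_name = "setup"

    def record(path: Path) -> Path:
        manifest.outputs.append(str(path))
        return path

    try:
        # ---- data stage -------------------------------------------------
        stage_name = "data"
        if config.roster_path:
            path = Path(config.roster_path)
            roster = (
                read_roster_xlsx(path)
                if path.suffix.lower() in (".xlsx", ".xls")
                else ProjectRoster.read_csv(path)
            )
            manifest.input_hashes["roster"] = _hash_file(path)
        elif config.use_reference_roster:
            roster = reference_roster()
            manifest.notes["roster"] = "synthetic reference roster"
        else:
            roster = generate_roster(syn)
            manifest.notes["roster"] = "synthetic"
        roster.write_csv(record(out / "roster.csv"))

        if config.assessments_path:
            tables = {
                s: AssessmentTable.read_csv(config.assessments_path, stage=s)
                for s in ("initial", "final")
            }
            manifest.input_hashes["assessments"] = _hash_file(config.assessments_path)
            assignment = {
                pid: tables[config.stage].reviewers_of(pid) for pid in roster.ids
            }
        else:
            if syn.n_projects != roster.n_projects:
                syn = dataclasses.replace(
                    syn,
                    n_projects=roster.n_projects,
                    platform_sizes=tuple(
                        sum(1 for t in roster.platform_types if t == p)
                        for p in roster.platforms
                    ),
                )
            assignment = assign_reviewers(syn, roster)
            tables = generate_assessments(syn, assignment)
            manifest.notes["assessments"] = "synthetic"
        combined = pd.concat([tables["initial"].frame, tables["final"].frame])
        combined.to_csv(record(out / "assessments.csv"), index=False)

        # ---- PoS stage --------------------------------------------------
        stage_name = "pos"
        pos_by_stage = {}
        for s, table in tables.items():
            rng = substream(config.seed, f"pos-{s}")
            pos_by_stage[s] = simulate_project_pos(
                table, assignment, roster, n_iter=config.n_iterations, rng=rng
            )
        summary = pd.concat([p.summary_frame() for p in pos_by_stage.values()])
        summary.to_csv(record(out / "pos_summary.csv"), index=False)
        pos = pos_by_stage[config.stage]

        # ---- preference stage -------------------------------------------
        stage_name = "preference"
        levels = default_attribute_levels()
        if config.part_worths_path:
            pw = PartWorths.from_json(config.part_worths_path)
            manifest.input_hashes["part_worths"] = _hash_file(config.part_worths_path)
        elif config.choices_path or config.fit_dce:
            if config.choices_path:
                choices = ChoiceData.read_csv(config.choices_path)
                manifest.input_hashes["choices"] = _hash_file(config.choices_path)
            else:
                design = build_design(
                    levels,
                    syn.dce.blocks,
                    syn.dce.sets_per_block,
                    syn.dce.alternatives_per_set,
                    rng=substream(config.seed, "design"),
                )
                choices = generate_choice_responses(syn, design, syn.dce.true_part_worths)
                choices.write_csv(record(out / "choices.csv"))
                validity = validity_checks(choices, design)
                manifest.notes["dce_validity"] = {
                    "dominance_pass_rate": validity.dominance_pass_rate,
                    "consistency_pass_rate": validity.consistency_pass_rate,
                }
            pw = fit_conditional_logit(choices, levels)
        else:
            pw = default_part_worths()
            manifest.notes["part_worths"] = "published fixture (preference fit skipped)"
        pw.to_json(record(out / "part_worths.json"))

        # ---- valuation + optimization -----------------------------------
        stage_name = "optimize"
        pw_draws = sample_part_worths(
            pw, config.n_iterations, substream(config.seed, "part-worths")
        )
        evaluator = PortfolioEvaluator(roster, pos, pw_draws, levels)
        spec = OptimizationSpec(
            budget=config.budget,
            objective=config.objective,
            q=config.q,
            n_iterations=config.n_iterations,
            seed=config.seed,
            solver=config.solver,
        )
        solver = enumerate_optimal if config.solver == "enumerate" else evolve_optimal
        solution = solver(roster, pos, pw_draws, levels, spec, evaluator=evaluator)
        sol_payload = {
            "project_ids": list(solution.portfolio.project_ids(roster)),
            "cost_musd": solution.portfolio.cost,
            "objective": solution.objective,
            "mean": solution.summary.mean,
            "ci_low": solution.summary.ci_low,
            "ci_high": solution.summary.ci_high,
            "trace": solution.trace,
        }
        record(out / "solution.json").write_text(json.dumps(sol_payload, indent=2))

        # ---- frontier ----------------------------------------------------
        stage_name = "frontier"
        points = build_frontier(
            roster, pos, pw_draws, levels, spec=spec, evaluator=evaluator
        )
        frontier_frame(points, roster).to_csv(record(out / "frontier.csv"), index=False)
        comparator = pos_to_cost_ranking(roster, pos, config.budget)
        record(out / "pos_to_cost.json").write_text(
            json.dumps(
                {
                    "project_ids": list(comparator.project_ids(roster)),
                    "cost_musd": comparator.cost,
                    "mean": value_summary(
                        evaluator.value_draws_for_mask(comparator.mask)
                    ).mean,
                },
                indent=2,
            )
        )
        curves = pd.concat(
            [
                platform_value_curve(roster, pos, pw_draws, levels, platform)
                for platform in roster.platforms
            ]
        )
        curves.to_csv(record(out / "platform_curves.csv"), index=False)

        # ---- uncertainty -------------------------------------------------
        stage_name = "uncertainty"
        alternatives = enumerate_feasible(roster, config.budget)
        stats_rows = []
        for p in alternatives:
            st = dominance_stats(evaluator.value_draws_for_mask(p.mask))
            stats_rows.append(
                {
                    "project_ids": "+".join(p.project_ids(roster)),
                    "cost_musd": p.cost,
                    "mean": st.mean,
                    "variance": st.variance,
                    "semivariance": st.semivariance,
                    "sd": st.sd,
                    "mad": st.mad,
                    "gini": st.gini,
                    "mean_minus_gini": st.mean_minus_gini,
                }
            )
        pd.DataFrame(stats_rows).to_csv(record(out / "dominance.csv"), index=False)
        report = outranking_report(
            solution.portfolio, alternatives, pos, pw_draws, levels, roster,
            evaluator=evaluator,
        )
        report.table.to_csv(record(out / "rank_probabilities.csv"), index=False)
        report.inclusion.to_csv(record(out / "rank_bands.csv"), index=False)

        manifest.notes["n_feasible_alternatives"] = len(alternatives)
        manifest.write(out / "manifest.json")
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage_name}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed in stage {stage_name!r}: {exc}") from exc
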