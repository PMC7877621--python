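"""Probability-of-success model.

Reviewers score each project on seven factors (C1 applicant competency, C2
project feasibility, C3 clinical benefit, C4 safety potential, C5
manufacturing scalability & speed, C6 operational suitability, C7 operational
sustainability) with three-point estimates (worst, most-likely, best) on
[0, 1]. Each triple defines a triangular distribution. A Monte Carlo
simulation turns the reviewer mixture into a distribution of project PoS:
in each iteration one reviewer of the project is drawn uniformly, each
factor is sampled from that reviewer's triangular distribution, and the
project PoS is the product of the seven factor draws (the factors are
treated as consequentially independent). Platform-level success is the
probability that at least one selected member project succeeds,

    POS_{>=1}(k) = 1 - prod_i (1 - p_ik),

computed iteration-wise so that downstream portfolio comparisons share
common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .roster import Portfolio, ProjectRoster

__all__ = [
    "FACTORS",
    "TriangularSpec",
    "AssessmentTable",
    "ProjectPoSDraws",
    "PlatformSuccessDraws",
    "DrawSummary",
    "sample_triangular",
    "simulate_project_pos",
    "platform_success_draws",
    "summarize_draws",
]

#: The seven PoS factors.
FACTORS: tuple[str, ...] = ("C1", "C2", "C3", "C4", "C5", "C6", "C7")

ASSESSMENT_COLUMNS = (
    "reviewer_id",
    "project_id",
    "factor",
    "worst",
    "most_likely",
    "best",
    "stage",
)


@dataclass(frozen=True)
class TriangularSpec:
    """Three-point estimate (low, mode, high) on [0, 1].

    A degenerate spec with ``low == high`` is a point mass.
    """

    low: float
    mode: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low <= self.mode <= self.high <= 1.0):
            raise ValueError(
                f"triangular spec requires 0 <= low <= mode <= high <= 1, "
                f"got ({self.low}, {self.mode}, {self.high})"
            )


def _triangular_ppf(
    u: np.ndarray, low: np.ndarray, mode: np.ndarray, high: np.ndarray
) -> np.ndarray:
    """Inverse CDF of the triangular distribution, vectorized.

    Degenerate intervals (low == high) collapse to a point mass at ``low``.
    """
    u = np.asarray(u, dtype=float)
    low = np.broadcast_to(np.asarray(low, dtype=float), u.shape)
    mode = np.broadcast_to(np.asarray(mode, dtype=float), u.shape)
    high = np.broadcast_to(np.asarray(high, dtype=float), u.shape)
    span = high - low
    safe_span = np.where(span > 0, span, 1.0)
    fc = np.where(span > 0, (mode - low) / safe_span, 0.0)
    left = low + np.sqrt(np.clip(u * safe_span * (mode - low), 0.0, None))
    right = high - np.sqrt(np.clip((1.0 - u) * safe_span * (high - mode), 0.0, None))
    x = np.where(u < fc, left, right)
    return np.where(span > 0, x, low)


def sample_triangular(
    spec: TriangularSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` samples from a triangular three-point estimate.

    Sampling is by inverse CDF, so the draws are a deterministic function of
    the generator's uniform stream.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    u = rng.random(n)
    return _triangular_ppf(u, spec.low, spec.mode, spec.high)


class AssessmentTable:
    """Three-point factor estimates, keyed by (reviewer, project, factor).

    Stored in long format with columns ``reviewer_id, project_id, factor,
    worst, most_likely, best, stage``. Every reviewer-project pair must carry
    all seven factors.
    """

    def __init__(self, frame: pd.DataFrame, stage: str = "initial"):
        missing = [c for c in ASSESSMENT_COLUMNS if c not in frame.columns and c != "stage"]
        if missing:
            raise ValueError(f"assessment table missing columns {missing}")
        frame = frame.copy()
        if "stage" not in frame.columns:
            frame["stage"] = stage
        stages = frame["stage"].unique()
        if len(stages) > 1:
            raise ValueError(
                f"an AssessmentTable holds a single stage; found {sorted(stages)}"
            )
        self.stage = str(stages[0]) if len(stages) else stage
        bad = frame["factor"][~frame["factor"].isin(FACTORS)].unique()
        if len(bad):
            raise ValueError(f"unknown factors {sorted(bad)}; expected {list(FACTORS)}")
        for col in ("worst", "most_likely", "best"):
            vals = pd.to_numeric(frame[col], errors="coerce")
            if vals.isna().any() or (vals < 0).any() or (vals > 1).any():
                raise ValueError(f"column {col!r} must be numeric in [0, 1]")
            frame[col] = vals
        if ((frame["worst"] > frame["most_likely"]) | (frame["most_likely"] > frame["best"])).any():
            raise ValueError("triples must satisfy worst <= most_likely <= best")
        counts = frame.groupby(["reviewer_id", "project_id"])["factor"].nunique()
        if (counts != len(FACTORS)).any():
            incomplete = counts[counts != len(FACTORS)].index.tolist()
            raise ValueError(
                f"every reviewer-project pair needs all {len(FACTORS)} factors; "
                f"incomplete pairs: {incomplete[:5]}"
            )
        self.frame = frame.reset_index(drop=True)
        self._cache: dict[tuple[str, str], np.ndarray] = {}

    def reviewers_of(self, project_id: str) -> tuple[str, ...]:
        sub = self.frame[self.frame["project_id"] == project_id]
        return tuple(sorted(sub["reviewer_id"].unique()))

    def triples(self, reviewer_id: str, project_id: str) -> np.ndarray:
        """(7, 3) array of (worst, most_likely, best) ordered C1..C7."""
        key = (reviewer_id, project_id)
        if key not in self._cache:
            sub = self.frame[
                (self.frame["reviewer_id"] == reviewer_id)
                & (self.frame["project_id"] == project_id)
            ]
            if sub.empty:
                raise KeyError(f"no assessment for reviewer {reviewer_id!r} on {project_id!r}")
            sub = sub.set_index("factor").loc[list(FACTORS)]
            self._cache[key] = sub[["worst", "most_likely", "best"]].to_numpy(dtype=float)
        return self._cache[key]

    def write_csv(self, path: str | Path) -> None:
        self.frame[list(ASSESSMENT_COLUMNS)].to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, stage: str | None = None) -> "AssessmentTable":
        frame = pd.read_csv(path)
        if stage is not None and "stage" in frame.columns:
            frame = frame[frame["stage"] == stage]
        return cls(frame)


@dataclass(frozen=True, eq=False)
class ProjectPoSDraws:
    """Monte Carlo project-PoS samples: iterations x projects, in [0, 1]."""

    samples: np.ndarray
    project_ids: tuple[str, ...]
    stage: str = "initial"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2 or samples.shape[1] != len(self.project_ids):
            raise ValueError("samples must be (iterations, n_projects)")
        if samples.size and (samples.min() < 0 or samples.max() > 1):
            raise ValueError("PoS samples must lie in [0, 1]")

    @property
    def n_iter(self) -> int:
        return self.samples.shape[0]

    def mean_by_project(self) -> pd.Series:
        return pd.Series(self.samples.mean(axis=0), index=list(self.project_ids))

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for j, pid in enumerate(self.project_ids):
            s = summarize_draws(self.samples[:, j])
            rows.append(
                {
                    "project_id": pid,
                    "stage": self.stage,
                    "mean": s.mean,
                    "sd": s.sd,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True, eq=False)
class PlatformSuccessDraws:
    """Iteration-wise POS>=1 samples per platform type."""

    samples: np.ndarray
    platforms: tuple[str, ...]

    @property
    def n_iter(self) -> int:
        return self.samples.shape[0]


def _normalize_assignment(assignment) -> Mapping[str, Sequence[str]]:
    if hasattr(assignment, "by_project"):
        return assignment.by_project
    return assignment


def simulate_project_pos(
    assessments: AssessmentTable,
    assignment: Mapping[str, Sequence[str]],
    roster: ProjectRoster,
    n_iter: int = 10_000,
    rng: np.random.Generator | None = None,
) -> ProjectPoSDraws:
    """Simulate project PoS from the reviewer mixture.

    Per iteration and project: one assigned reviewer is selected uniformly at
    random, each of the seven factors is drawn from that reviewer's
    triangular distribution, and the draws are multiplied.
    """
    if rng is None:
        rng = np.random.default_rng()
    assignment = _normalize_assignment(assignment)
    n = roster.n_projects
    draws = np.empty((n_iter, n))
    for j, pid in enumerate(roster.ids):
        reviewers = list(assignment.get(pid, ()))
        if not reviewers:
            raise ValueError(f"project {pid!r} has no assigned reviewers")
        params = np.stack([assessments.triples(r, pid) for r in reviewers])  # (R, 7, 3)
        ridx = rng.integers(0, len(reviewers), size=n_iter)
        u = rng.random((n_iter, len(FACTORS)))
        low = params[ridx, :, 0]
        mode = params[ridx, :, 1]
        high = params[ridx, :, 2]
        factor_draws = _triangular_ppf(u, low, mode, high)
        draws[:, j] = factor_draws.prod(axis=1)
    return ProjectPoSDraws(samples=draws, project_ids=roster.ids, stage=assessments.stage)


def platform_success_draws(
    pos: ProjectPoSDraws, roster: ProjectRoster, selection: Portfolio
) -> PlatformSuccessDraws:
    """Iteration-wise POS>=1 per platform for the selected projects.

    Computed on the draws themselves (common random numbers), not on their
    means: POS>=1(k) = 1 - prod over selected members of (1 - p_ik). A
    platform with no selected member yields 0.
    """
    if selection.selection.size != roster.n_projects:
        raise ValueError("selection length must equal roster size")
    platforms = roster.platforms
    out = np.zeros((pos.n_iter, len(platforms)))
    for kk, platform in enumerate(platforms):
        idx = [i for i in roster.members(platform) if selection.selection[i]]
        if idx:
            out[:, kk] = 1.0 - np.prod(1.0 - pos.samples[:, idx], axis=1)
    return PlatformSuccessDraws(samples=out, platforms=platforms)


@dataclass(frozen=True)
class DrawSummary:
    mean: float
    sd: float
    ci_low: float
    ci_high: float


def summarize_draws(samples: np.ndarray, ci: float = 0.95) -> DrawSummary:
    """Mean, sample SD and equal-tailed percentile interval of MC draws."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("cannot summarize empty draws")
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    sd = float(samples.std(ddof=1)) if samples.size > 1 else 0.0
    return DrawSummary(mean=float(samples.mean()), sd=sd, ci_low=float(lo), ci_high=float(hi))
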