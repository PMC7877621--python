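"""Project rosters and portfolio selections.

A roster lists the candidate platform-technology projects under evaluation:
an id, the platform type the project belongs to (RNA, viral vector, DNA,
protein or gene-encoded mAb), and its budget in US$ million. A portfolio is
a binary selection over the roster with its total cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["PLATFORMS", "ProjectRoster", "Portfolio"]

#: Canonical platform-type names, in the order used throughout.
PLATFORMS: tuple[str, ...] = ("RNA", "Viral Vector", "DNA", "Protein", "mAb")

ROSTER_COLUMNS = ("project_id", "platform_type", "budget_musd")


@dataclass(frozen=True, eq=False)
class ProjectRoster:
    """Candidate projects: ids, platform types and budgets (US$ million)."""

    ids: tuple[str, ...]
    platform_types: tuple[str, ...]
    budgets: np.ndarray

    def __post_init__(self) -> None:
        budgets = np.asarray(self.budgets, dtype=float)
        object.__setattr__(self, "budgets", budgets)
        if not (len(self.ids) == len(self.platform_types) == budgets.size):
            raise ValueError("ids, platform_types and budgets must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("project ids must be unique")
        if budgets.size and not np.all(budgets > 0):
            raise ValueError("budgets must be strictly positive (US$ million)")

    @property
    def n_projects(self) -> int:
        return len(self.ids)

    @property
    def platforms(self) -> tuple[str, ...]:
        """Platform types present, canonical order first, then first-appearance."""
        present = set(self.platform_types)
        ordered = [p for p in PLATFORMS if p in present]
        for p in self.platform_types:
            if p not in ordered:
                ordered.append(p)
        return tuple(ordered)

    def members(self, platform: str) -> np.ndarray:
        """Indices of the projects belonging to ``platform``."""
        if platform not in self.platform_types:
            raise KeyError(f"unknown platform type: {platform!r}")
        return np.array([i for i, p in enumerate(self.platform_types) if p == platform])

    @property
    def total_budget(self) -> float:
        return float(self.budgets.sum())

    def index_of(self, project_id: str) -> int:
        try:
            return self.ids.index(project_id)
        except ValueError:
            raise KeyError(f"unknown project id: {project_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "project_id": self.ids,
                "platform_type": self.platform_types,
                "budget_musd": self.budgets,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ProjectRoster":
        missing = [c for c in ROSTER_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(
                f"roster table is missing columns {missing}; expected {list(ROSTER_COLUMNS)}"
            )
        budgets = pd.to_numeric(frame["budget_musd"], errors="coerce")
        if budgets.isna().any():
            bad = frame.index[budgets.isna()].tolist()
            raise ValueError(f"non-numeric budget in rows {bad}")
        return cls(
            ids=tuple(str(v) for v in frame["project_id"]),
            platform_types=tuple(str(v) for v in frame["platform_type"]),
            budgets=budgets.to_numpy(dtype=float),
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ProjectRoster":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True, eq=False)
class Portfolio:
    """A binary selection of roster projects with its total cost (US$ million)."""

    selection: np.ndarray
    cost: float
    label: str = ""

    def __post_init__(self) -> None:
        sel = np.asarray(self.selection, dtype=bool)
        object.__setattr__(self, "selection", sel)

    @classmethod
    def from_selection(
        cls, roster: ProjectRoster, selection: Iterable[bool | int], label: str = ""
    ) -> "Portfolio":
        sel = np.asarray(list(selection), dtype=bool)
        if sel.size != roster.n_projects:
            raise ValueError("selection length must equal roster size")
        return cls(selection=sel, cost=float(roster.budgets[sel].sum()), label=label)

    @classmethod
    def from_ids(
        cls, roster: ProjectRoster, project_ids: Sequence[str], label: str = ""
    ) -> "Portfolio":
        sel = np.zeros(roster.n_projects, dtype=bool)
        for pid in project_ids:
            sel[roster.index_of(pid)] = True
        return cls(selection=sel, cost=float(roster.budgets[sel].sum()), label=label)

    @classmethod
    def from_mask(cls, roster: ProjectRoster, mask: int, label: str = "") -> "Portfolio":
        sel = np.array([(mask >> i) & 1 for i in range(roster.n_projects)], dtype=bool)
        return cls(selection=sel, cost=float(roster.budgets[sel].sum()), label=label)

    @property
    def n_selected(self) -> int:
        return int(self.selection.sum())

    @property
    def mask(self) -> int:
        return int(sum(1 << i for i, s in enumerate(self.selection) if s))

    def project_ids(self, roster: ProjectRoster) -> tuple[str, ...]:
        return tuple(pid for pid, s in zip(roster.ids, self.selection) if s)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Portfolio):
            return NotImplemented
        return bool(
            self.selection.size == other.selection.size
            and np.all(self.selection == other.selection)
        )

    def __hash__(self) -> int:
        return hash(self.selection.tobytes())
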