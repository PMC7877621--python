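"""Discrete choice experiment and platform preference model.

Stakeholders choose between portfolio alternatives described by the
platform-level probability of at least one success, POS>=1(k), shown at one
of three levels per platform (lower a = 0, middle b, upper c). Choices are
analysed with a conditional logit whose utility is

    U_j = sum_k [ beta_b(k) X_b(k) + beta_c(k) X_c(k) ],

under cumulative (level-threshold) coding: X_b(k) = 1 if the alternative
shows level b or c on platform k, X_c(k) = 1 only at level c. beta_b(k) is
therefore the part-worth of moving a -> b and beta_c(k) the increment
b -> c.

The fitted part-worths define a piecewise preference weight for platform k
at an arbitrary POS>=1 value p:

    w_k(p) = beta_b / (b - a)                                  if p <= b
    w_k(p) = (beta_b + beta_c * (p - b) / (c - b)) / p         if p >  b

so that w_k(p) * p interpolates linearly through (0, 0), (b, beta_b) and
(c, beta_b + beta_c). Coefficient uncertainty is propagated by sampling each
coefficient from a Normal(estimate, SE) distribution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .roster import PLATFORMS

__all__ = [
    "AttributeLevels",
    "ChoiceDesign",
    "ChoiceData",
    "PartWorths",
    "PartWorthDraws",
    "ValidityReport",
    "build_design",
    "fit_conditional_logit",
    "validity_checks",
    "preference_weight",
    "value_contribution",
    "sample_part_worths",
    "default_part_worths",
    "default_attribute_levels",
]

#: Table of POS>=1 attribute levels (a, b, c) per platform used in the survey.
_DEFAULT_LEVELS: dict[str, tuple[float, float, float]] = {
    "RNA": (0.0, 0.30, 0.60),
    "Viral Vector": (0.0, 0.30, 0.60),
    "DNA": (0.0, 0.28, 0.56),
    "Protein": (0.0, 0.20, 0.40),
    "mAb": (0.0, 0.06, 0.12),
}

#: Published part-worth estimates (coefficient, SE) per platform and segment.
_DEFAULT_PART_WORTHS: dict[str, tuple[float, float, float, float]] = {
    # platform: (beta_b, se_b, beta_c, se_c)
    "RNA": (1.313, 0.081, 0.360, 0.070),
    "Viral Vector": (1.167, 0.082, 0.463, 0.070),
    "DNA": (0.833, 0.076, 0.118, 0.073),
    "Protein": (0.710, 0.077, 0.266, 0.075),
    "mAb": (0.133, 0.073, -0.043, 0.076),
}


def slug(platform: str) -> str:
    return platform.lower().replace(" ", "_").replace("-", "_")


@dataclass(frozen=True)
class AttributeLevels:
    """POS>=1 levels (a, b, c) per platform type, each in [0, 1] with a < b < c."""

    levels: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for platform, (a, b, c) in self.levels.items():
            if not (0.0 <= a < b < c <= 1.0):
                raise ValueError(
                    f"levels for {platform!r} must satisfy 0 <= a < b < c <= 1, got {(a, b, c)}"
                )

    @property
    def platforms(self) -> tuple[str, ...]:
        return tuple(self.levels.keys())

    def __getitem__(self, platform: str) -> tuple[float, float, float]:
        return tuple(self.levels[platform])


def default_attribute_levels() -> AttributeLevels:
    """The survey's attribute levels for the five platform types."""
    return AttributeLevels(levels=dict(_DEFAULT_LEVELS))


@dataclass(frozen=True, eq=False)
class ChoiceDesign:
    """A blocked choice-set design.

    ``sets[b][s]`` is a (n_alternatives, n_platforms) array of POS>=1 level
    values shown in block ``b``, set ``s``; columns follow ``platforms``.
    """

    levels: AttributeLevels
    platforms: tuple[str, ...]
    sets: tuple[tuple[np.ndarray, ...], ...]

    @property
    def n_blocks(self) -> int:
        return len(self.sets)

    @property
    def sets_per_block(self) -> int:
        return len(self.sets[0])

    @property
    def n_alternatives(self) -> int:
        return self.sets[0][0].shape[0]

    def set_id(self, block: int, s: int) -> str:
        return f"B{block + 1}S{s + 1:02d}"

    def dominant_alternative(self, block: int, s: int) -> int | None:
        """Index of a level-wise dominant alternative in the set, if any."""
        mat = self.sets[block][s]
        for j in range(mat.shape[0]):
            dominant = True
            for o in range(mat.shape[0]):
                if o == j:
                    continue
                if not (np.all(mat[j] >= mat[o]) and np.any(mat[j] > mat[o])):
                    dominant = False
                    break
            if dominant:
                return j
        return None

    def dominant_sets(self) -> dict[str, int]:
        out = {}
        for b in range(self.n_blocks):
            for s in range(self.sets_per_block):
                j = self.dominant_alternative(b, s)
                if j is not None:
                    out[self.set_id(b, s)] = j
        return out

    def repeated_sets(self) -> list[tuple[str, str]]:
        """Pairs of identical sets within a block (consistency probes)."""
        pairs = []
        for b in range(self.n_blocks):
            block = self.sets[b]
            for s1 in range(len(block)):
                for s2 in range(s1 + 1, len(block)):
                    if np.array_equal(block[s1], block[s2]):
                        pairs.append((self.set_id(b, s1), self.set_id(b, s2)))
        return pairs

    def diagnostics(self) -> dict:
        """Level balance and pairwise level co-occurrence counts."""
        stacked = np.vstack([m for block in self.sets for m in block])
        balance = {}
        for kk, platform in enumerate(self.platforms):
            a, b, c = self.levels[platform]
            col = stacked[:, kk]
            balance[platform] = {
                "a": int(np.sum(np.isclose(col, a))),
                "b": int(np.sum(np.isclose(col, b))),
                "c": int(np.sum(np.isclose(col, c))),
            }
        cooccurrence = {}
        for k1 in range(len(self.platforms)):
            for k2 in range(k1 + 1, len(self.platforms)):
                key = f"{self.platforms[k1]}|{self.platforms[k2]}"
                counts = np.zeros((3, 3), dtype=int)
                l1 = _level_codes(stacked[:, k1], self.levels[self.platforms[k1]])
                l2 = _level_codes(stacked[:, k2], self.levels[self.platforms[k2]])
                for i, j in zip(l1, l2):
                    counts[i, j] += 1
                cooccurrence[key] = counts.tolist()
        return {
            "balance": balance,
            "cooccurrence": cooccurrence,
            "n_dominant_sets": len(self.dominant_sets()),
            "n_repeated_sets": len(self.repeated_sets()),
        }

    def participant_permutations(
        self, n_participants: int, rng: np.random.Generator
    ) -> list[dict]:
        """Per-participant randomization: block, set order and attribute order."""
        out = []
        for p in range(n_participants):
            block = p % self.n_blocks
            out.append(
                {
                    "block": block,
                    "set_order": rng.permutation(self.sets_per_block).tolist(),
                    "attribute_order": rng.permutation(len(self.platforms)).tolist(),
                }
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in range(self.n_blocks):
            for s in range(self.sets_per_block):
                mat = self.sets[b][s]
                for j in range(mat.shape[0]):
                    row = {"block": b + 1, "set_id": self.set_id(b, s), "alternative_id": j + 1}
                    for kk, platform in enumerate(self.platforms):
                        row[f"level_{slug(platform)}"] = mat[j, kk]
                    rows.append(row)
        return pd.DataFrame(rows)


def _level_codes(col: np.ndarray, abc: tuple[float, float, float]) -> np.ndarray:
    a, b, c = abc
    codes = np.full(col.shape, -1, dtype=int)
    for code, v in enumerate((a, b, c)):
        codes[np.isclose(col, v)] = code
    if (codes < 0).any():
        raise ValueError("level value not among the platform's (a, b, c)")
    return codes


def build_design(
    levels: AttributeLevels,
    blocks: int = 2,
    sets_per_block: int = 16,
    alts: int = 3,
    rng: np.random.Generator | None = None,
) -> ChoiceDesign:
    """Generate a randomized, level-balanced blocked choice design.

    For every platform the three levels appear with frequencies balanced
    within +/-1 across all alternatives of the design. Balance and
    co-occurrence diagnostics are available from the returned design.
    """
    if alts < 2:
        raise ValueError("a choice set needs at least 2 alternatives")
    if blocks < 1 or sets_per_block < 1:
        raise ValueError("blocks and sets_per_block must be positive")
    if rng is None:
        rng = np.random.default_rng()
    platforms = levels.platforms
    total = blocks * sets_per_block * alts
    columns = []
    for platform in platforms:
        a, b, c = levels[platform]
        codes = np.resize(np.array([0, 1, 2]), total)
        rng.shuffle(codes)
        columns.append(np.array([a, b, c])[codes])
    stacked = np.column_stack(columns)  # (total, n_platforms)
    sets = []
    idx = 0
    for _ in range(blocks):
        block = []
        for _ in range(sets_per_block):
            block.append(stacked[idx : idx + alts].copy())
            idx += alts
        sets.append(tuple(block))
    return ChoiceDesign(levels=levels, platforms=platforms, sets=tuple(sets))


class ChoiceData:
    """Long-format choice responses.

    Columns: ``participant_id, block, set_id, alternative_id``, one
    ``level_<platform>`` column per platform holding the POS>=1 level shown,
    and ``chosen`` (0/1). Exactly one alternative is chosen per participant
    and set.
    """

    def __init__(self, frame: pd.DataFrame, platforms: Sequence[str]):
        self.platforms = tuple(platforms)
        required = ["participant_id", "set_id", "alternative_id", "chosen"] + [
            f"level_{slug(p)}" for p in self.platforms
        ]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"choice data missing columns {missing}")
        chosen_per_set = frame.groupby(["participant_id", "set_id"])["chosen"].sum()
        if (chosen_per_set != 1).any():
            raise ValueError("exactly one alternative must be chosen per participant and set")
        self.frame = frame.reset_index(drop=True)

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, platforms: Sequence[str] = PLATFORMS) -> "ChoiceData":
        return cls(pd.read_csv(path), platforms)


def design_matrix(
    level_values: np.ndarray, platforms: Sequence[str], levels: AttributeLevels
) -> np.ndarray:
    """Cumulative-coded regressors: per platform, X_b = 1(level >= b), X_c = 1(level >= c)."""
    cols = []
    for kk, platform in enumerate(platforms):
        a, b, c = levels[platform]
        col = level_values[:, kk]
        cols.append((col >= b - 1e-12).astype(float))
        cols.append((col >= c - 1e-12).astype(float))
    return np.column_stack(cols)


@dataclass(frozen=True)
class PartWorths:
    """Fitted (or fixed) part-worth coefficients per platform.

    ``beta_b[k]`` is the a -> b part-worth, ``beta_c[k]`` the b -> c
    increment; SEs accompany each. ``cov`` (optional) is the 2t x 2t
    coefficient covariance in the order (b, c) within each platform.
    """

    platforms: tuple[str, ...]
    beta_b: Mapping[str, float]
    se_b: Mapping[str, float]
    beta_c: Mapping[str, float]
    se_c: Mapping[str, float]
    cov: np.ndarray | None = None
    diagnostics: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for platform in self.platforms:
            if self.se_b[platform] < 0 or self.se_c[platform] < 0:
                raise ValueError("standard errors must be non-negative")

    @property
    def coef_names(self) -> tuple[str, ...]:
        names = []
        for p in self.platforms:
            names.extend([f"{p}:b", f"{p}:c"])
        return tuple(names)

    @property
    def coef_vector(self) -> np.ndarray:
        out = []
        for p in self.platforms:
            out.extend([self.beta_b[p], self.beta_c[p]])
        return np.array(out)

    @property
    def se_vector(self) -> np.ndarray:
        out = []
        for p in self.platforms:
            out.extend([self.se_b[p], self.se_c[p]])
        return np.array(out)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "platforms": list(self.platforms),
            "coefficients": {
                p: {
                    "beta_b": self.beta_b[p],
                    "se_b": self.se_b[p],
                    "beta_c": self.beta_c[p],
                    "se_c": self.se_c[p],
                }
                for p in self.platforms
            },
            "diagnostics": dict(self.diagnostics),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PartWorths":
        payload = json.loads(Path(path).read_text())
        coefs = payload["coefficients"]
        platforms = tuple(payload["platforms"])
        return cls(
            platforms=platforms,
            beta_b={p: coefs[p]["beta_b"] for p in platforms},
            se_b={p: coefs[p]["se_b"] for p in platforms},
            beta_c={p: coefs[p]["beta_c"] for p in platforms},
            se_c={p: coefs[p]["se_c"] for p in platforms},
            diagnostics=payload.get("diagnostics", {}),
        )


def default_part_worths() -> PartWorths:
    """The published part-worth estimates for the five platform types."""
    platforms = tuple(_DEFAULT_PART_WORTHS.keys())
    return PartWorths(
        platforms=platforms,
        beta_b={p: _DEFAULT_PART_WORTHS[p][0] for p in platforms},
        se_b={p: _DEFAULT_PART_WORTHS[p][1] for p in platforms},
        beta_c={p: _DEFAULT_PART_WORTHS[p][2] for p in platforms},
        se_c={p: _DEFAULT_PART_WORTHS[p][3] for p in platforms},
    )


class SeparationError(RuntimeError):
    """Raised when the conditional-logit likelihood is unbounded."""


def fit_conditional_logit(
    data: ChoiceData,
    levels: AttributeLevels,
    max_iter: int = 100,
    tol: float = 1e-6,
    start: np.ndarray | None = None,
) -> PartWorths:
    """Maximum-likelihood conditional logit fit of the choice data.

    Newton-Raphson on the (concave) grouped-softmax log-likelihood with
    cumulative level coding; converged when the gradient's max-norm falls
    below ``tol``. Standard errors come from the inverse observed
    information.
    """
    platforms = data.platforms
    frame = data.frame.sort_values(["participant_id", "set_id", "alternative_id"])
    level_values = frame[[f"level_{slug(p)}" for p in platforms]].to_numpy(dtype=float)
    X = design_matrix(level_values, platforms, levels)
    y = frame["chosen"].to_numpy(dtype=float)
    group_keys = (frame["participant_id"].astype(str) + "||" + frame["set_id"].astype(str)).to_numpy()
    # contiguous group start offsets
    change = np.nonzero(np.r_[True, group_keys[1:] != group_keys[:-1]])[0]
    n_groups = change.size
    k = X.shape[1]

    # identification: any regressor constant within every group is inestimable
    group_mean = np.add.reduceat(X, change, axis=0) / np.diff(np.r_[change, X.shape[0]])[:, None]
    expanded = np.repeat(group_mean, np.diff(np.r_[change, X.shape[0]]), axis=0)
    centered = X - expanded
    col_var = (centered**2).sum(axis=0)
    names = []
    for p in platforms:
        names.extend([f"{p}:b", f"{p}:c"])
    dead = [names[j] for j in range(k) if col_var[j] < 1e-12]
    if dead:
        raise ValueError(f"no within-set variation in regressors {dead}; model is rank-deficient")
    if np.linalg.matrix_rank(centered) < k:
        raise ValueError("rank-deficient design matrix: collinear cumulative-coded columns")

    beta = np.zeros(k) if start is None else np.asarray(start, dtype=float).copy()

    def loglik_parts(b):
        eta = X @ b
        # stable softmax per group
        gmax = np.maximum.reduceat(eta, change)
        eta_c = eta - np.repeat(gmax, np.diff(np.r_[change, X.shape[0]]))
        ex = np.exp(eta_c)
        denom = np.add.reduceat(ex, change)
        p = ex / np.repeat(denom, np.diff(np.r_[change, X.shape[0]]))
        ll = float(np.sum(np.log(p[y > 0.5])))
        return ll, p

    ll, p = loglik_parts(beta)
    converged = False
    for _ in range(max_iter):
        grad = X.T @ (y - p)
        A = X * p[:, None]
        M = np.add.reduceat(A, change, axis=0)  # group-wise sum of p*x = xbar under p
        info = X.T @ A - M.T @ M
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix: complete separation or unbounded likelihood"
            ) from exc
        # step-halving line search
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new, p_new = loglik_parts(cand)
            if ll_new >= ll - 1e-12:
                beta, ll, p = cand, ll_new, p_new
                break
            scale *= 0.5
        if np.max(np.abs(beta)) > 30:
            raise SeparationError(
                "coefficients diverging: complete separation in the choice data"
            )
    else:
        grad = X.T @ (y - p)
        if np.max(np.abs(grad)) < tol:
            converged = True
    if not converged:
        raise SeparationError("conditional logit did not converge (gradient norm above tol)")

    A = X * p[:, None]
    M = np.add.reduceat(A, change, axis=0)
    info = X.T @ A - M.T @ M
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    # on separated data the gradient vanishes as probabilities saturate, so
    # Newton "converges" at an absurd scale with exploding standard errors
    if np.max(np.abs(beta)) > 15 or not np.all(np.isfinite(se)) or np.max(se) > 100:
        raise SeparationError(
            "degenerate fit (|coefficient| or SE implausibly large): "
            "complete or quasi-complete separation in the choice data"
        )

    n = n_groups
    aic = 2 * k - 2 * ll
    aicc = aic + (2 * k * (k + 1)) / max(n - k - 1, 1)
    bic = k * np.log(n) - 2 * ll
    diagnostics = {
        "loglik": ll,
        "aicc": aicc,
        "bic": bic,
        "n_choice_sets": float(n),
        "converged": float(converged),
    }
    beta_b = {p_: beta[2 * i] for i, p_ in enumerate(platforms)}
    beta_c = {p_: beta[2 * i + 1] for i, p_ in enumerate(platforms)}
    se_b = {p_: float(se[2 * i]) for i, p_ in enumerate(platforms)}
    se_c = {p_: float(se[2 * i + 1]) for i, p_ in enumerate(platforms)}
    return PartWorths(
        platforms=tuple(platforms),
        beta_b=beta_b,
        se_b=se_b,
        beta_c=beta_c,
        se_c=se_c,
        cov=cov,
        diagnostics=diagnostics,
    )


@dataclass(frozen=True)
class ValidityReport:
    """Per-participant dominance and consistency results with summary rates."""

    per_participant: pd.DataFrame
    dominance_applicable: bool
    consistency_applicable: bool
    dominance_pass_rate: float | None
    consistency_pass_rate: float | None


def validity_checks(data: ChoiceData, design: ChoiceDesign) -> ValidityReport:
    """Internal validity: dominance and consistency test pass rates.

    Dominance: on sets containing a level-wise dominant alternative, did the
    participant choose it? Consistency: on repeated (identical) sets within a
    block, did the participant make the same choice? When the design has no
    probe of a kind, the corresponding check reports not-applicable.
    """
    dominant = design.dominant_sets()
    repeats = design.repeated_sets()
    chosen = (
        data.frame[data.frame["chosen"] == 1]
        .set_index(["participant_id", "set_id"])["alternative_id"]
        .sort_index()
    )
    rows = []
    for pid, sub in chosen.groupby(level=0):
        answered = {sid: int(alt) for (_, sid), alt in sub.items()}
        n_dom = n_dom_pass = 0
        for sid, dom_alt in dominant.items():
            if sid in answered:
                n_dom += 1
                # alternative ids are 1-based in the data
                n_dom_pass += int(answered[sid] == dom_alt + 1)
        n_rep = n_rep_pass = 0
        for sid_a, sid_b in repeats:
            if sid_a in answered and sid_b in answered:
                n_rep += 1
                n_rep_pass += int(answered[sid_a] == answered[sid_b])
        rows.append(
            {
                "participant_id": pid,
                "n_dominance": n_dom,
                "n_dominance_passed": n_dom_pass,
                "n_repeats": n_rep,
                "n_consistent": n_rep_pass,
            }
        )
    table = pd.DataFrame(rows)
    dom_total = int(table["n_dominance"].sum()) if len(table) else 0
    rep_total = int(table["n_repeats"].sum()) if len(table) else 0
    return ValidityReport(
        per_participant=table,
        dominance_applicable=dom_total > 0,
        consistency_applicable=rep_total > 0,
        dominance_pass_rate=(
            float(table["n_dominance_passed"].sum() / dom_total) if dom_total else None
        ),
        consistency_pass_rate=(
            float(table["n_consistent"].sum() / rep_total) if rep_total else None
        ),
    )


def preference_weight(beta_b, beta_c, levels_k: tuple[float, float, float], pos):
    """Piecewise preference weight w_k at a POS>=1 value.

    Below or at the middle level b the weight is the constant slope
    ``beta_b / (b - a)``; above b it blends in the b -> c increment so that
    ``w * pos`` is the linear interpolation through (b, beta_b) and
    (c, beta_b + beta_c). Values above c continue the upper segment.
    """
    a, b, c = levels_k
    if not b > a:
        raise ValueError("levels must satisfy b > a")
    if not c > b:
        raise ValueError("levels must satisfy c > b")
    pos_arr = np.asarray(pos, dtype=float)
    beta_b = np.asarray(beta_b, dtype=float)
    beta_c = np.asarray(beta_c, dtype=float)
    lower = np.broadcast_to(beta_b / (b - a), np.broadcast_shapes(pos_arr.shape, beta_b.shape))
    safe_pos = np.where(pos_arr > b, pos_arr, 1.0)
    upper = (beta_b + beta_c * (pos_arr - b) / (c - b)) / safe_pos
    w = np.where(pos_arr > b, upper, lower)
    if np.ndim(pos) == 0 and np.ndim(beta_b) == 0 and np.ndim(beta_c) == 0:
        return float(w)
    return w


def value_contribution(beta_b, beta_c, levels_k: tuple[float, float, float], pos):
    """w_k(pos) * pos, computed directly on the value scale (no division)."""
    a, b, c = levels_k
    if not (b > a and c > b):
        raise ValueError("levels must satisfy a < b < c")
    pos_arr = np.asarray(pos, dtype=float)
    beta_b = np.asarray(beta_b, dtype=float)
    beta_c = np.asarray(beta_c, dtype=float)
    lower = beta_b * pos_arr / (b - a)
    upper = beta_b + beta_c * (pos_arr - b) / (c - b)
    out = np.where(pos_arr > b, upper, lower)
    if np.ndim(pos) == 0 and np.ndim(beta_b) == 0 and np.ndim(beta_c) == 0:
        return float(out)
    return out


@dataclass(frozen=True, eq=False)
class PartWorthDraws:
    """Monte Carlo coefficient draws: per platform, (n_iter,) vectors."""

    platforms: tuple[str, ...]
    beta_b: Mapping[str, np.ndarray]
    beta_c: Mapping[str, np.ndarray]

    @property
    def n_iter(self) -> int:
        return len(next(iter(self.beta_b.values())))

    @classmethod
    def point(cls, pw: PartWorths, n_iter: int) -> "PartWorthDraws":
        """Degenerate draws fixed at the point estimates."""
        return cls(
            platforms=pw.platforms,
            beta_b={p: np.full(n_iter, pw.beta_b[p]) for p in pw.platforms},
            beta_c={p: np.full(n_iter, pw.beta_c[p]) for p in pw.platforms},
        )


def sample_part_worths(
    pw: PartWorths,
    n: int,
    rng: np.random.Generator,
    multivariate: bool = False,
) -> PartWorthDraws:
    """Sample coefficient uncertainty: Normal(estimate, SE) per coefficient.

    With ``multivariate=True`` and a covariance available, draws come from
    the joint Normal instead (logit estimates are correlated).
    """
    for p in pw.platforms:
        if pw.se_b[p] is None or pw.se_c[p] is None or np.isnan(pw.se_b[p]) or np.isnan(pw.se_c[p]):
            raise ValueError(f"missing standard error for platform {p!r}")
    if multivariate:
        if pw.cov is None:
            raise ValueError("multivariate sampling requires a coefficient covariance")
        draws = rng.multivariate_normal(pw.coef_vector, pw.cov, size=n)
        beta_b = {p: draws[:, 2 * i] for i, p in enumerate(pw.platforms)}
        beta_c = {p: draws[:, 2 * i + 1] for i, p in enumerate(pw.platforms)}
    else:
        beta_b = {}
        beta_c = {}
        for p in pw.platforms:
            beta_b[p] = pw.beta_b[p] + pw.se_b[p] * rng.standard_normal(n)
            beta_c[p] = pw.beta_c[p] + pw.se_c[p] * rng.standard_normal(n)
    return PartWorthDraws(platforms=pw.platforms, beta_b=beta_b, beta_c=beta_c)
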