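"""Portfolio value distribution.

The value of a portfolio is the preference-weighted sum over platform types,

    V_p = sum_k w_k(POS>=1(k)) * POS>=1(k),

evaluated iteration-wise in a Monte Carlo simulation: each iteration pairs a
project-PoS draw with a part-worth coefficient draw (common random numbers),
computes the platform-level POS>=1 for the selected members, applies the
piecewise preference weight at that realized POS>=1, and sums across
platforms.

:class:`PortfolioEvaluator` caches, per platform, the contribution draws of
every membership pattern (2^s vectors for a platform with s member
projects), so that any portfolio's value draws are a sum of one cached
vector per platform. Enumeration over all feasible portfolios and the
genetic search both run on this cache, guaranteeing that every portfolio is
compared on identical draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pos import DrawSummary, PlatformSuccessDraws, ProjectPoSDraws, platform_success_draws
from .preference import AttributeLevels, PartWorthDraws, value_contribution
from .roster import Portfolio, ProjectRoster

__all__ = ["ValueDraws", "ValueSummary", "portfolio_value_draws", "value_summary", "PortfolioEvaluator", "empirical_quantile"]


@dataclass(frozen=True, eq=False)
class ValueDraws:
    """Monte Carlo samples of a portfolio's value V_p."""

    samples: np.ndarray
    portfolio: Portfolio

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not np.all(np.isfinite(samples)):
            raise ValueError("value draws must be finite")

    @property
    def n_iter(self) -> int:
        return self.samples.size


def portfolio_value_draws(
    pos: ProjectPoSDraws,
    pw_draws: PartWorthDraws,
    portfolio: Portfolio,
    levels: AttributeLevels,
    roster: ProjectRoster,
) -> ValueDraws:
    """Iteration-wise portfolio value draws under common random numbers.

    Raises if the PoS draws and coefficient draws disagree on the iteration
    count, which would silently decouple the common-random-number pairing.
    """
    if pos.n_iter != pw_draws.n_iter:
        raise ValueError(
            f"iteration mismatch: {pos.n_iter} PoS draws vs {pw_draws.n_iter} coefficient draws"
        )
    platform_draws = platform_success_draws(pos, roster, portfolio)
    total = np.zeros(pos.n_iter)
    for kk, platform in enumerate(platform_draws.platforms):
        p = platform_draws.samples[:, kk]
        a, b, c = levels[platform]
        if np.any(p > c + 1e-12):
            warnings.warn(
                f"POS>=1 for {platform} exceeds the upper survey level {c}; "
                "extrapolating the upper preference segment",
                stacklevel=2,
            )
        total += value_contribution(
            pw_draws.beta_b[platform], pw_draws.beta_c[platform], (a, b, c), p
        )
    return ValueDraws(samples=total, portfolio=portfolio)


def empirical_quantile(samples: np.ndarray, q: float) -> float:
    """Inverted-CDF (type-1) empirical quantile, for exact reproducibility."""
    if not 0.0 < q < 1.0:
        raise ValueError("quantile level must lie in (0, 1)")
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("cannot take the quantile of empty draws")
    k = max(int(np.ceil(q * samples.size)) - 1, 0)
    return float(np.partition(samples, k)[k])


@dataclass(frozen=True, eq=False)
class ValueSummary:
    """Mean, SD, percentile CI and a quantile accessor of value draws."""

    mean: float
    sd: float
    ci_low: float
    ci_high: float
    _sorted: np.ndarray

    def quantile(self, q: float) -> float:
        k = max(int(np.ceil(q * self._sorted.size)) - 1, 0)
        return float(self._sorted[k])


def value_summary(v: ValueDraws | np.ndarray, ci: float = 0.95) -> ValueSummary:
    samples = v.samples if isinstance(v, ValueDraws) else np.asarray(v, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("cannot summarize empty draws")
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    sd = float(samples.std(ddof=1)) if samples.size > 1 else 0.0
    return ValueSummary(
        mean=float(samples.mean()),
        sd=sd,
        ci_low=float(lo),
        ci_high=float(hi),
        _sorted=np.sort(samples),
    )


class PortfolioEvaluator:
    """Cached iteration-wise value contributions for every platform pattern.

    Portfolio encodings are bit masks over the roster; the contribution of
    platform k depends only on which of its member projects are selected
    (its pattern), so all 2^s_k patterns are precomputed once.
    """

    def __init__(
        self,
        roster: ProjectRoster,
        pos: ProjectPoSDraws,
        pw_draws: PartWorthDraws,
        levels: AttributeLevels,
    ):
        if pos.n_iter != pw_draws.n_iter:
            raise ValueError("PoS draws and coefficient draws must share the iteration count")
        self.roster = roster
        self.n_iter = pos.n_iter
        self.platforms = roster.platforms
        self._members: list[np.ndarray] = []
        self._contrib: list[np.ndarray] = []  # (2^s, n_iter) per platform
        self._contrib_mean: list[np.ndarray] = []
        for platform in self.platforms:
            idx = roster.members(platform)
            s = idx.size
            if s > 20:
                raise ValueError(
                    f"platform {platform!r} has {s} member projects; the "
                    "2^s pattern cache is infeasible beyond 20"
                )
            fail = np.ones((1 << s, pos.n_iter))
            for pattern in range(1, 1 << s):
                low = pattern & -pattern
                j = low.bit_length() - 1
                fail[pattern] = fail[pattern ^ low] * (1.0 - pos.samples[:, idx[j]])
            p_draws = 1.0 - fail
            a, b, c = levels[platform]
            contrib = value_contribution(
                pw_draws.beta_b[platform][None, :],
                pw_draws.beta_c[platform][None, :],
                (a, b, c),
                p_draws,
            )
            self._members.append(idx)
            self._contrib.append(contrib)
            self._contrib_mean.append(contrib.mean(axis=1))

    def pattern_ids(self, masks: np.ndarray) -> list[np.ndarray]:
        """Per platform, the membership-pattern index for each roster mask."""
        masks = np.asarray(masks, dtype=np.int64)
        out = []
        for idx in self._members:
            pat = np.zeros_like(masks)
            for j, i in enumerate(idx):
                pat |= ((masks >> int(i)) & 1) << j
            out.append(pat)
        return out

    def value_draws_for_mask(self, mask: int) -> np.ndarray:
        pats = self.pattern_ids(np.array([mask]))
        total = np.zeros(self.n_iter)
        for contrib, pat in zip(self._contrib, pats):
            total += contrib[int(pat[0])]
        return total

    def value_draws(self, portfolio: Portfolio) -> ValueDraws:
        return ValueDraws(
            samples=self.value_draws_for_mask(portfolio.mask), portfolio=portfolio
        )

    def mean_values(self, masks: np.ndarray) -> np.ndarray:
        """Expected V_p for each mask (exact under the cached draws)."""
        pats = self.pattern_ids(masks)
        total = np.zeros(len(np.asarray(masks)))
        for mean, pat in zip(self._contrib_mean, pats):
            total += mean[pat]
        return total

    def objective_values(
        self,
        masks: np.ndarray,
        objective: str = "expected",
        q: float = 0.95,
        chunk: int = 1024,
    ) -> np.ndarray:
        """Objective (mean or type-1 q-quantile of V_p) for each mask."""
        masks = np.asarray(masks, dtype=np.int64)
        if objective == "expected":
            return self.mean_values(masks)
        if objective != "quantile":
            raise ValueError(f"unknown objective {objective!r}")
        if not 0.0 < q < 1.0:
            raise ValueError("quantile level must lie in (0, 1)")
        k = max(int(np.ceil(q * self.n_iter)) - 1, 0)
        pats = self.pattern_ids(masks)
        out = np.empty(masks.size)
        for start in range(0, masks.size, chunk):
            stop = min(start + chunk, masks.size)
            acc = np.zeros((stop - start, self.n_iter))
            for contrib, pat in zip(self._contrib, pats):
                acc += contrib[pat[start:stop]]
            out[start:stop] = np.partition(acc, k, axis=1)[:, k]
        return out
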