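# Methods

This note documents the modelling choices, defaults and numerical
conventions behind vaxfolio, and what the synthetic data generator does and
does not emulate.

## Probability-of-success model

Project PoS is the product of seven factor probabilities (C1–C7). The
factors are treated as consequentially independent — the judgement that, for
example, staff competency failure is independent of technical failure was
built into the factor definitions — so multiplication is the aggregation
rule. Reviewer disagreement is preserved, not averaged away: in each Monte
Carlo iteration one of the project's assigned reviewers is drawn uniformly,
and each factor is sampled from that reviewer's triangular (worst,
most-likely, best) distribution. Reviewers are drawn independently across
projects within an iteration, because review panels differ by project; no
reviewer calibration or weighting is applied.

Triangular sampling uses the closed-form inverse CDF on a uniform stream, so
draws are a pure function of the substream state; degenerate triples
(worst = best) are point masses. The default iteration count is 10,000.
Summaries report the mean, sample SD and an equal-tailed *percentile*
interval (a Normal-approximate interval would misrepresent the strongly
skewed product distributions).

## Random numbers

One master seed feeds named substreams (CRC-32 of a label such as
`pos-final` or `part-worths`). All portfolio comparisons — both solvers, the
frontier, dominance statistics and rank probabilities — share a single PoS
draw matrix and a single coefficient draw matrix (common random numbers).
This makes comparisons reflect structural differences rather than sampling
noise, makes the genetic algorithm's objective exactly commensurable with
the enumerated optimum, and makes every result bit-reproducible from the
seed.

## Preference model

The conditional logit uses cumulative (level-threshold) coding: X_b(k) = 1
when platform *k* is shown at its middle or upper POS≥1 level, X_c(k) = 1
only at the upper level. Under this coding β_b(k) is literally the part-worth
of the a→b gain and β_c(k) the b→c increment, matching how the published
coefficient table is labelled; plain dummy coding would change the
coefficients' meaning. Estimation is Newton–Raphson on the grouped-softmax
log-likelihood (concave), with step-halving, convergence at gradient
max-norm < 1e-6, and SEs from the inverse observed information. Complete or
quasi-complete separation is detected two ways: divergence during iteration,
and implausible post-convergence scale (|β| > 15 or SE > 100) — on separated
data the gradient vanishes as probabilities saturate, so a gradient test
alone would "converge".

The piecewise preference weight w_k(p) makes w_k(p)·p the linear
interpolation through (0, 0), (b, β_b) and (c, β_b + β_c). Below b the
weight is the constant slope β_b/(b − a) (also returned at p = 0). Above c
the upper segment is extrapolated linearly and a warning is emitted: the
survey never showed levels above c, so values there borrow the last observed
marginal utility. This matters in practice for the mAb platform, whose upper
level is 0.12 while two simulated projects can exceed it, and whose fitted
b→c increment is negative — negative coefficients are retained, not
truncated, so adding an mAb project can lower value above the middle level.
Coefficient uncertainty defaults to independent Normal(β̂, SE) draws per
coefficient; a multivariate option uses the fitted covariance, since logit
estimates are correlated.

The design generator produces a randomized level-balanced design (each
platform's three levels appear with frequencies within ±1 across the
design), with balance and pairwise co-occurrence diagnostics, naturally
occurring dominance probes and repeated-set detection for the dominance and
consistency validity checks. It is not D-optimal; the study's design came
from commercial software and only balance/orthogonality assessment is
described, which the diagnostics reproduce.

## Optimization

The selection problem maximizes either the Monte Carlo mean of V_p or an
empirical quantile. The chance-constraint phrasing in the original study is
ambiguous between "the 95th percentile of V_p" and "a 95%-confidence
worst case" (the 5th percentile); the implementation takes the configurable
quantile level q (default 0.95), so both readings are one flag apart, and
quantiles use the inverted-CDF (type-1) definition for exact
reproducibility. The mean objective is also retained for comparison runs.

Enumeration evaluates every feasible subset through a per-platform pattern
cache: platform *k* with s_k members has 2^{s_k} membership patterns whose
contribution draws are precomputed once, so any portfolio's value draws are
a sum of five cached vectors. Ties are broken by lower cost, then the
lexicographically smallest selection vector. The guard for enumeration is
24 projects.

The genetic algorithm uses a binary chromosome, tournament selection (size
3), uniform crossover (rate 0.9), per-bit mutation (rate 1/n), elitism of
one, a death penalty (−∞) for over-budget chromosomes, and stops after 150
generations or 30 without improvement (population 96). Death-penalty
handling was chosen over repair because feasibility is easy to hit at the
default problem size. The GA shares the enumeration's evaluator, so its
objective can never exceed the enumerated optimum.

The efficiency frontier, under enumeration, is exact and compact: masks are
sorted by cost and a frontier point is emitted at every cost breakpoint
where the running optimum improves. The PoS-to-cost comparator ranks
projects by mean PoS per US$ million and greedily adds affordable projects,
*skipping* unaffordable ones and continuing down the list (rather than
stopping at the first miss); the skip-and-continue rule is stated here
because the ranking heuristic it mimics is described only loosely.
Platform value curves report, for m = 1..s_k, the best m-subset of a
platform by mean value — one interpretation of "incrementally increasing the
number of projects".

## Uncertainty analysis

Feasible alternatives under the budget are enumerated exactly (with a
strict-< flag for "strictly under budget" counts); this replaces the
study's ≈40,000 marginally-perturbed optimization runs with a complete and
cheaper equivalent at n = 16. Dispersion statistics use the population
variance, below-mean semivariance E[min(0, X − μ)²], mean absolute
deviation, and the Gini mean difference in Yitzhaki's convention
Γ = E|X − X′|/2, computed with the exact sorted-rank identity
Γ = n⁻² Σ_i (2i − 1 − n) x_(i) (O(n log n), equal to the naive double loop
to machine precision). Mean-risk dominance requires a weakly better mean and
weakly smaller risk with one strict; mean-Gini dominance compares (μ, μ − Γ).
Rank probabilities count ties as half-wins, which makes
P(A≻B) + P(B≻A) = 1 exactly and a portfolio's probability against itself
0.5. The outranking report bands probabilities (default [0.5, 0.75],
(0.75, 0.9], (0.9, 1.0], with a catch band below 0.5) and tabulates
per-band project inclusion frequencies.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study's *structure*: 16 projects grouped
4/4/3/3/2 across RNA, viral vector, DNA, protein and gene-encoded mAb;
budgets uniform on US$ 6–65 million rounded to 0.1 (the study reports only
the range and median, not the generator); a 27-reviewer pool with 4–5
reviewers per project and per-reviewer loads of 3–4 (applied to reviewers
actually used — the published pool size and load ranges are arithmetically
incompatible if every pool member must carry a full load); triangular factor
triples; and survey responses drawn from a conditional logit with the
published coefficients as the default truth.

Factor priors default to a most-likely value ~ Beta(8, 2) (optimistic expert
modes, mean 0.8, so seven-factor products land in the low-PoS regime the
analysis operates in) with a symmetric half-width ~ U(0.05, 0.30) clipped to
[0, 1]. The "final versus initial assessment" revision is modelled as
multiplicative shrinkage of all three triple points by (1 − optimism_shift),
default 0.2 — a mechanism-free stand-in for the observed downward revisions
that compounds across the seven factors and pushes final platform POS≥1
below the survey mid-levels, as reported for the final assessments.

Not emulated: reviewer psychology, correlation of a reviewer's beliefs
across factors or projects (independence is assumed throughout), platform-
or project-specific quality differences, respondent heterogeneity or
inattention in the survey, and the actual confidential budgets (the
reference roster's budgets are synthetic values matching only the published
summary statistics). Passing tests therefore demonstrate that the *method*
behaves correctly under the study's structural conditions — recovery,
oracle equivalence, dominance and robustness logic — not that any specific
substantive result of the real data is reproduced; counts that depend on the
exact budgets (such as the number of feasible alternatives under a budget)
are properties of the synthetic roster.

## Numerical conventions and edge cases

* Monetary values are US$ million throughout; no discounting or currency
  conversion.
* Budgets in the generator are rounded to 0.1 then clipped so rounding never
  escapes the configured range.
* Empty portfolios are feasible at any positive budget and have value 0;
  when the budget is below the cheapest project both solvers return the
  empty portfolio (the GA with a warning).
* A platform with no selected member contributes POS≥1 = 0 and value 0.
* Degenerate GA settings (population 1, no crossover or mutation) return
  the better of the initial chromosome and the empty portfolio.
* AICc and BIC use the number of choice sets as the sample size.
* The run pipeline writes a manifest (tool version, config hash, input
  hashes, seeds, output inventory); rerunning with the same seed and inputs
  reproduces all numeric outputs bit-identically (timestamps aside).

## Problem sizes used in the shipped checks

The test suite and acceptance script run the full method at the study's
iteration count (10,000) for the headline analysis, and use 2,000-iteration
Monte Carlo with 16-project instances for the repeated solver-agreement
sweeps, 5,000 simulated respondents for the recovery check, and 50
replicate surveys of 1,000 respondents for interval coverage — sizes chosen
to keep the whole suite comfortably fast while leaving Monte Carlo error
well inside the asserted tolerances.
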