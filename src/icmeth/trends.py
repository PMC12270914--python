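"""Age-trend statistics: Spearman correlations, sex-difference tests and
continuous two-phase (hinge) regression for the age of decline."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ContractError, DegenerateDomainError

__all__ = ["TwoPhaseFit", "spearman_with_p", "sex_difference_test", "two_phase_fit"]

_EXACT_MAX = 10  # both groups at or below this size -> exact enumeration


@dataclass(frozen=True)
class TwoPhaseFit:
    """Continuous two-segment least-squares fit of score on age."""

    breakpoint: float
    intercept: float
    slope1: float
    slope2: float
    rss: float


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman rho (mid-ranks for ties) with a two-sided t-approximation p.

    p is computed from ``t = rho * sqrt((n-2) / (1-rho**2))`` on n-2
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ContractError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ContractError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ContractError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDomainError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _ranksum_exact_p(ranks: np.ndarray, n1: int, observed: float) -> float:
    # Two-sided exact p: enumerate every assignment of n1 of the pooled
    # mid-ranks to group 1 and count sums at least as far from the mean.
    mu = n1 * (ranks.size + 1) / 2.0
    dev = abs(observed - mu)
    hits = total = 0
    for combo in itertools.combinations(ranks, n1):
        total += 1
        if abs(sum(combo) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def sex_difference_test(score, labels) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between the two label groups.

    Uses exact enumeration when both groups have at most 10 members and a
    tie-corrected normal approximation otherwise. Returns the rank-sum
    statistic W of the first group (sorted label order) and the p value.
    """
    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels)
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ContractError(f"need exactly two groups, got {levels}")
    m1 = labels == levels[0]
    n1, n2 = int(m1.sum()), int((~m1).sum())
    if n1 == 0 or n2 == 0:
        raise ContractError("both groups must be nonempty")
    ranks = stats.rankdata(score)
    w = float(ranks[m1].sum())
    if n1 <= _EXACT_MAX and n2 <= _EXACT_MAX:
        return w, _ranksum_exact_p(ranks, n1, w)
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    # tie correction on the rank variance
    _, counts = np.unique(score, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return w, 1.0
    z = (w - mu) / np.sqrt(var)
    return w, float(2.0 * stats.norm.sf(abs(z)))


def two_phase_fit(
    age,
    score,
    grid_step: float = 1.0,
    interior_quantile: float = 0.05,
) -> TwoPhaseFit:
    """Exhaustive grid search for a continuous hinge regression breakpoint.

    For each candidate c, fits ``score ~ b0 + b1*age + b2*max(0, age-c)``
    by least squares; returns the candidate minimizing RSS. Candidates are
    multiples of ``grid_step`` strictly inside the [interior_quantile,
    1 - interior_quantile] age quantile range (the outer ages are excluded
    to avoid boundary degeneracy). Ties in RSS (within a tolerance scaled
    to the score's total sum of squares) are broken toward the smallest
    breakpoint.
    """
    age = np.asarray(age, dtype=float)
    score = np.asarray(score, dtype=float)
    if age.shape != score.shape:
        raise ContractError("age and score must have equal length")
    n = age.size
    if n < 6:
        raise ContractError("need at least 6 observations")
    lo = float(np.quantile(age, interior_quantile))
    hi = float(np.quantile(age, 1.0 - interior_quantile))
    if hi - lo <= 2 * grid_step:
        raise ContractError("age span too narrow for the requested grid step")
    # snap candidates to multiples of grid_step so round breakpoints are hit
    start = np.ceil(lo / grid_step) * grid_step
    grid = np.arange(start, hi + 1e-9, grid_step)
    grid = grid[(grid > age.min()) & (grid < age.max())]
    if grid.size == 0:
        raise ContractError("empty breakpoint grid")

    # ties in RSS (within a data-scaled tolerance) keep the earlier, smaller c
    tol = 1e-10 * (1.0 + float(np.sum((score - score.mean()) ** 2)))
    best = None
    for c in grid:
        X = np.column_stack([np.ones(n), age, np.maximum(0.0, age - c)])
        coef, _, rank, _ = np.linalg.lstsq(X, score, rcond=None)
        if rank < 3:
            continue
        rss = float(np.sum((score - X @ coef) ** 2))
        if best is None or rss < best[0] - tol:
            best = (rss, float(c), coef)
    if best is None:
        raise DegenerateDomainError("all candidate hinge designs were singular")
    rss, c, coef = best
    return TwoPhaseFit(
        breakpoint=c,
        intercept=float(coef[0]),
        slope1=float(coef[1]),
        slope2=float(coef[1] + coef[2]),
        rss=rss,
    )
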