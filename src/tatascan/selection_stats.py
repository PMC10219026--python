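"""Selection-mode and summary statistics.

Exact one-sided binomial tests with Bonferroni correction (the
neutral-drift and concordance comparisons), the lowest-bar sign test for
"which subset has the smallest mean", a small-sample exact Mann-Whitney U,
a two-sample z test on means with SEMs, and mean +/- SEM summaries.

All directional tests are one-sided in the direction of the observed
excess; two-sided variants are available by flag.  The Bonferroni
multiplicity ``m`` defaults to 1 and is supplied by callers (for the
marker-level summaries it is the number of candidate markers in the run).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


class StatError(ValueError):
    pass


@dataclass(frozen=True)
class CountSplit:
    """A directional count pair (e.g. worsen vs relief, increase vs decrease)."""

    label: str
    k_a: int
    k_b: int

    def __post_init__(self) -> None:
        if self.k_a < 0 or self.k_b < 0:
            raise StatError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.k_a + self.k_b


@dataclass(frozen=True)
class TestResult:
    """A raw one-tailed probability with its Bonferroni-adjusted value."""

    statistic: float
    p_raw: float
    m: int
    method: str
    side: str = ""
    extras: dict = field(default_factory=dict, compare=False)

    @property
    def p_adj(self) -> float:
        return bonferroni(self.p_raw, self.m)


def binom_tail(k: int, n: int, theta: float, side: str) -> float:
    """Exact binomial tail probability P(X <= k) (``side='le'``) or
    P(X >= k) (``side='ge'``) for X ~ Binomial(n, theta)."""
    if not 0 <= k <= n:
        raise StatError(f"k={k} outside 0..{n}")
    if not 0 < theta < 1:
        raise StatError("theta must be in (0, 1)")
    if side == "le":
        return float(sps.binom.cdf(k, n, theta))
    if side == "ge":
        return float(sps.binom.sf(k - 1, n, theta))
    raise StatError(f"side must be 'le' or 'ge', got {side!r}")


def bonferroni(p_raw: float, m: int) -> float:
    if m < 1:
        raise StatError("Bonferroni multiplicity must be >= 1")
    return min(1.0, m * p_raw)


def direction_bias_test(
    split: CountSplit, theta0: float, m: int = 1, *, two_sided: bool = False
) -> TestResult:
    """Exact binomial test of a directional split against a reference ratio.

    ``theta0`` is the null probability of the ``k_a`` direction (for the
    neutral-drift comparison, the whole-genome ratio of affinity-raising to
    all affinity-changing promoter SNPs; it has no default because it is an
    external input).  The tail is taken in the direction of the observed
    excess relative to ``theta0``.
    """
    if split.n == 0:
        raise StatError("empty split")
    expected = split.n * theta0
    side = "ge" if split.k_a >= expected else "le"
    p = binom_tail(split.k_a, split.n, theta0, side)
    if two_sided:
        p = min(1.0, 2 * p)
    return TestResult(
        statistic=float(split.k_a),
        p_raw=p,
        m=m,
        method="exact-binomial",
        side="two-sided" if two_sided else side,
        extras={"theta0": theta0, "n": split.n},
    )


def deg_concordance_test(split: CountSplit, m: int = 1) -> TestResult:
    """One-sided exact binomial at theta=0.5 on a (worsen, relief) split."""
    return direction_bias_test(split, 0.5, m)


def lowest_bar_sign_test(
    subset_means: Sequence[float], focal_index: int, m: int = 1
) -> TestResult:
    """Sign test that one subset's mean is the lowest of all subsets.

    Under the null that each of the ``s`` subsets is equally likely to have
    the smallest mean... the focal subset being strictly lowest has
    probability 0.5**(s-1) under independent pairwise coin flips; if the
    focal mean is not strictly below every other (including ties), p = 1.
    """
    s = len(subset_means)
    if s < 2:
        raise StatError("need at least 2 subsets")
    focal = subset_means[focal_index]
    others = [v for i, v in enumerate(subset_means) if i != focal_index]
    tie = any(math.isclose(focal, v) for v in others)
    lowest = all(focal < v for v in others) and not tie
    p = 0.5 ** (s - 1) if lowest else 1.0
    return TestResult(
        statistic=float(focal),
        p_raw=p,
        m=m,
        method="lowest-bar-sign",
        extras={"n_subsets": s, "tie": tie, "focal_is_lowest": lowest},
    )


def _mw_u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """U for sample x: number of (x_i, y_j) pairs with x_i > y_j (+0.5 per tie)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mannwhitney_u(
    x: Sequence[float],
    y: Sequence[float],
    *,
    alternative: str = "two-sided",
    exact_max_n: int = 8,
) -> TestResult:
    """Mann-Whitney U test with an exact small-sample path.

    With ``min(len(x), len(y)) <= exact_max_n`` and no ties across the
    pooled sample, the null distribution of U is computed by full
    enumeration of all C(n1+n2, n1) labelings; otherwise the normal
    approximation with tie correction is used.  ``alternative='less'``
    tests whether x is stochastically smaller than y.
    """
    x, y = list(map(float, x)), list(map(float, y))
    if not x or not y:
        raise StatError("empty sample")
    u_obs = _mw_u_statistic(x, y)
    pooled = x + y
    no_ties = len(set(pooled)) == len(pooled)
    if min(len(x), len(y)) <= exact_max_n and no_ties:
        n1 = len(x)
        us = [
            _mw_u_statistic([pooled[i] for i in combo],
                            [pooled[i] for i in range(len(pooled)) if i not in combo])
            for combo in itertools.combinations(range(len(pooled)), n1)
        ]
        total = len(us)
        p_less = sum(u <= u_obs for u in us) / total
        p_greater = sum(u >= u_obs for u in us) / total
        method = "exact-enumeration"
    else:
        res_less = sps.mannwhitneyu(x, y, alternative="less", method="asymptotic")
        res_greater = sps.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        p_less, p_greater = float(res_less.pvalue), float(res_greater.pvalue)
        method = "normal-approximation"
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2 * min(p_less, p_greater))
    return TestResult(
        statistic=u_obs,
        p_raw=p,
        m=1,
        method=f"mann-whitney-u/{method}",
        side=alternative,
        extras={"n_x": len(x), "n_y": len(y)},
    )


def mean_z_test(
    mean_x: float, sem_x: float, mean_y: float, sem_y: float
) -> TestResult:
    """Two-sample z on means with standard errors (the parametric companion
    to the Mann-Whitney comparison; an interpretation, see the methods note)."""
    if sem_x <= 0 or sem_y <= 0:
        raise StatError("SEMs must be positive")
    z = abs(mean_x - mean_y) / math.hypot(sem_x, sem_y)
    return TestResult(
        statistic=z,
        p_raw=float(2 * sps.norm.sf(z)),
        m=1,
        method="mean-z",
        side="two-sided",
    )


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and standard error of the mean (sample SD / sqrt(n)).

    For a single value the SEM is undefined and returned as NaN.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise StatError("empty input")
    if v.size == 1:
        return float(v[0]), float("nan")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))
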