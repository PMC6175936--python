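"""Exact and resampling statistics shared by the behavioral and neural analyses.

The task's headline comparisons all rest on small-sample nonparametric
tests: a paired Wilcoxon signed-rank across sessions or neurons (N = 7-9,
where the minimum attainable two-sided exact p is ``2/2**n``), a two-sided
sign test per time bin for value-differentiation onsets, Welch t-tests, and
label-shuffling permutation tests.  The exact tests are computed by
enumeration/convolution rather than asymptotics so that printed p-values at
these sample sizes are exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "PermutationResult",
    "wilcoxon_signed_rank",
    "sign_test",
    "two_sample_t",
    "permutation_test",
    "paired_permutation_test",
]

logger = logging.getLogger(__name__)

#: use exhaustive enumeration in permutation tests when the number of
#: distinct relabelings is at most this
EXHAUSTIVE_LIMIT = 10_000

#: exact Wilcoxon null distribution by convolution up to this many nonzero
#: differences; normal approximation (tie-corrected) above
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test (two-sided)."""

    statistic: float
    p_two_sided: float
    n_effective: int
    method: str

    def __post_init__(self) -> None:
        if not (0.0 < self.p_two_sided <= 1.0):
            raise ValueError(f"p-value out of (0, 1]: {self.p_two_sided}")

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "p_two_sided": self.p_two_sided,
                "n_effective": self.n_effective, "method": self.method}


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a permutation test with add-one p-value.

    ``p >= 1/(n_permutations + 1)`` always; if ``exhaustive`` the p-value is
    exact over all distinct relabelings.
    """

    observed_stat: float
    n_permutations: int
    p_two_sided: float
    seed: Optional[int]
    exhaustive: bool

    def __post_init__(self) -> None:
        if self.p_two_sided < 1.0 / (self.n_permutations + 1) - 1e-12:
            raise ValueError("permutation p below its attainable minimum")

    def to_dict(self) -> dict:
        return {"observed_stat": self.observed_stat,
                "n_permutations": self.n_permutations,
                "p_two_sided": self.p_two_sided,
                "seed": self.seed, "exhaustive": self.exhaustive}


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_midranks(diffs: np.ndarray) -> np.ndarray:
    """Midranks of |diffs| (zeros already removed)."""
    return sps.rankdata(np.abs(diffs), method="average")


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank sum by convolution.

    Midranks are multiples of 1/2, so doubling them gives integers; the null
    distribution of the doubled positive-rank sum is built by convolving the
    two-point distributions of each term.
    """
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    top = 0
    for d in doubled:
        counts[d:top + d + 1] += counts[:top + 1]
        top += d
    counts /= 2.0 ** len(doubled)
    w2 = int(np.rint(2.0 * w_plus))
    p_low = counts[: w2 + 1].sum()
    p_high = counts[w2:].sum()
    return min(1.0, 2.0 * min(p_low, p_high))


def wilcoxon_signed_rank(diffs: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; ties among |differences| receive midranks.
    For up to 25 nonzero differences the two-sided p-value is exact
    (``2 * min(P(W+ <= w), P(W+ >= w))`` over all 2^n sign assignments,
    computed by convolution); beyond that, a tie-corrected normal
    approximation is used.  With n all-positive differences the attainable
    minimum is ``2/2**n`` — e.g. 0.00390625 at n = 9 and 0.015625 at n = 7.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("diffs must be a nonempty 1-D sequence")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; signed-rank test undefined")

    ranks = _signed_midranks(d)
    w_plus = float(ranks[d > 0].sum())

    if n <= WILCOXON_EXACT_MAX_N:
        p = _wilcoxon_exact_p(ranks, w_plus)
        method = "wilcoxon_exact"
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        # tie correction: subtract sum(t^3 - t)/48 over tied groups of |d|
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var -= float(np.sum(tie_counts ** 3 - tie_counts)) / 48.0
        if var <= 0:
            raise ValueError("degenerate variance in normal approximation")
        z = (w_plus - mean) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
        p = min(1.0, max(p, np.finfo(float).tiny))
        method = "wilcoxon_normal"
    return TestResult(statistic=w_plus, p_two_sided=p, n_effective=n, method=method)


# ---------------------------------------------------------------------------
# Sign test


def sign_test(n_pos: int, n_neg: int) -> TestResult:
    """Exact two-sided sign test on counts of positive/negative differences.

    Ties must already have been removed by the caller.  Under H0 the number
    of positives is Binomial(n, 1/2); the two-sided p-value is
    ``min(1, 2 * P(X <= min(n_pos, n_neg)))`` by symmetry.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be nonnegative")
    n = n_pos + n_neg
    if n == 0:
        raise ValueError("no nonzero differences; sign test undefined")
    k = min(n_pos, n_neg)
    p = min(1.0, 2.0 * float(sps.binom.cdf(k, n, 0.5)))
    return TestResult(statistic=float(n_pos), p_two_sided=p,
                      n_effective=n, method="sign_exact")


def sign_test_p(n_pos: np.ndarray, n_neg: np.ndarray) -> np.ndarray:
    """Vectorized exact two-sided sign-test p-values (NaN where n = 0).

    Used per time bin by the value-differentiation latency detector, where
    thousands of sign tests are evaluated along the grid.
    """
    n_pos = np.asarray(n_pos)
    n_neg = np.asarray(n_neg)
    n = n_pos + n_neg
    k = np.minimum(n_pos, n_neg)
    with np.errstate(invalid="ignore"):
        p = 2.0 * sps.binom.cdf(k, np.maximum(n, 1), 0.5)
    p = np.minimum(p, 1.0)
    return np.where(n > 0, p, np.nan)


# ---------------------------------------------------------------------------
# Welch t


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch's two-sample t-test (unequal variances), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.mean(a) == np.mean(b):
            return TestResult(statistic=0.0, p_two_sided=1.0,
                              n_effective=a.size + b.size, method="t_two_sample")
        raise ValueError("degenerate (zero) variance in both groups")
    stat, p = sps.ttest_ind(a, b, equal_var=False)
    p = min(1.0, max(float(p), np.finfo(float).tiny))
    return TestResult(statistic=float(stat), p_two_sided=p,
                      n_effective=a.size + b.size, method="t_two_sample")


# ---------------------------------------------------------------------------
# Permutation tests


def _mean_difference(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(a) - np.mean(b))


def permutation_test(group_a: Sequence[float], group_b: Sequence[float],
                     stat: str = "mean_difference", n_perm: int = 10_000,
                     seed: Optional[int] = None) -> PermutationResult:
    """Two-sample permutation test with group labels shuffled.

    The statistic is the difference of group means; the two-sided p-value
    uses the add-one rule ``(1 + #{|T*| >= |T_obs|}) / (n_perm + 1)`` so it
    can never be zero.  When the number of distinct relabelings
    ``C(n_a + n_b, n_a)`` is at most ``EXHAUSTIVE_LIMIT``, all of them are
    enumerated and the p-value is exact (``#{|T*| >= |T_obs|} / n_total``).
    """
    if stat != "mean_difference":
        raise ValueError(f"unsupported statistic {stat!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 100:
        logger.warning("permutation_test called with n_perm=%d < 100", n_perm)

    pooled = np.concatenate([a, b])
    n_a = a.size
    t_obs = _mean_difference(a, b)

    n_total = math.comb(pooled.size, n_a)
    if n_total <= EXHAUSTIVE_LIMIT:
        count = 0
        idx_all = np.arange(pooled.size)
        for idx in combinations(range(pooled.size), n_a):
            sel = np.zeros(pooled.size, dtype=bool)
            sel[list(idx)] = True
            t_star = _mean_difference(pooled[sel], pooled[~sel])
            if abs(t_star) >= abs(t_obs) - 1e-12:
                count += 1
        p = count / n_total
        return PermutationResult(observed_stat=t_obs, n_permutations=n_total,
                                 p_two_sided=max(p, 1.0 / n_total),
                                 seed=seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    count = 0
    # vectorized batch shuffling: argsort of uniforms gives random partitions
    batch = 512
    done = 0
    while done < n_perm:
        m = min(batch, n_perm - done)
        order = np.argsort(rng.random((m, pooled.size)), axis=1)
        perm = pooled[order]
        t_star = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
        count += int(np.sum(np.abs(t_star) >= abs(t_obs) - 1e-12))
        done += m
    p = (1 + count) / (n_perm + 1)
    return PermutationResult(observed_stat=t_obs, n_permutations=n_perm,
                             p_two_sided=p, seed=seed, exhaustive=False)


def paired_permutation_test(diffs: Sequence[float], n_perm: int = 10_000,
                            seed: Optional[int] = None) -> PermutationResult:
    """Sign-flipping permutation test on paired differences (mean statistic).

    The two-sided p-value follows the same add-one rule as
    :func:`permutation_test`; for n <= 13 pairs all ``2**n`` sign patterns
    are enumerated and the p-value is exact.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one paired difference")
    t_obs = float(np.mean(d))

    n_total = 2 ** d.size
    if n_total <= EXHAUSTIVE_LIMIT:
        signs = np.array([[1 if (m >> i) & 1 else -1 for i in range(d.size)]
                          for m in range(n_total)], dtype=float)
        t_star = signs @ d / d.size
        count = int(np.sum(np.abs(t_star) >= abs(t_obs) - 1e-12))
        p = count / n_total
        return PermutationResult(observed_stat=t_obs, n_permutations=n_total,
                                 p_two_sided=max(p, 1.0 / n_total),
                                 seed=seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    t_star = signs @ d / d.size
    count = int(np.sum(np.abs(t_star) >= abs(t_obs) - 1e-12))
    p = (1 + count) / (n_perm + 1)
    return PermutationResult(observed_stat=t_obs, n_permutations=n_perm,
                             p_two_sided=p, seed=seed, exhaustive=False)
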