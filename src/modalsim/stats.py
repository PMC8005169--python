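"""Hypothesis tests and exact interval estimators used by the simulations.

Two-group and k-group location tests (pooled/Welch t, Mann–Whitney, one-way
ANOVA + Tukey HSD, Kruskal–Wallis), the Fisher exact test for 2xk count
tables, and the Clopper–Pearson exact binomial confidence interval.

Every test returns a :class:`TestResult` with a two-sided p-value and the
direction of the effect, sign(center(a) - center(b)), because the
simulations track not only whether repeated experiments reach significance
but whether they agree on *which* group looks worse.

Degenerate inputs follow a documented convention instead of raising:
constant, identical groups give statistic 0 and p = 1 so that simulation
loops never crash on clamped point-mass samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln, stdtr

from .errors import (
    InsufficientDataError,
    InvalidCountsError,
    InvalidTableError,
    UnsupportedSizeError,
)

# switch from exact enumeration to the tie-corrected normal approximation
# when either group exceeds this size
MANN_WHITNEY_EXACT_MAX_N = 8

# refuse Freeman-Halton enumerations beyond these sizes
FISHER_MAX_K = 5
FISHER_MAX_TOTAL = 250


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    effect_direction: int  # sign of (mean/median of A - B); 0 allowed
    df: float | None = None


@dataclass(frozen=True)
class ProportionCi:
    successes: int
    trials: int
    level: float
    lower: float
    upper: float


def _sign(x: float) -> int:
    if x > 0:
        return 1
    if x < 0:
        return -1
    return 0


# ---------------------------------------------------------------------------
# Two-group tests
# ---------------------------------------------------------------------------

def t_test(a, b, variant: str = "pooled") -> TestResult:
    """Two-sided unpaired t-test, pooled ('Student') or Welch variance.

    Computed from the closed form (this is the hot path of the Monte Carlo
    engine); agreement with scipy.stats.ttest_ind is asserted in the test
    suite.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise InsufficientDataError("t_test needs >= 2 values per group")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = ma - mb
    if variant == "pooled":
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se2 = sp2 * (1.0 / na + 1.0 / nb)
    elif variant == "welch":
        se2 = va / na + vb / nb
        if se2 > 0:
            df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        else:
            df = na + nb - 2
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    if se2 == 0.0:
        if diff == 0.0:
            return TestResult(0.0, 1.0, 0, float(df))
        return TestResult(math.copysign(math.inf, diff), 0.0, _sign(diff), float(df))
    t = diff / math.sqrt(se2)
    p = 2.0 * stdtr(df, -abs(t))
    return TestResult(float(t), float(p), _sign(diff), float(df))


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration of rank splits.

    Enumerates all C(n1+n2, n1) assignments of the pooled (tied) values, so
    the null distribution of U is conditioned on the observed tie pattern.
    Two-sided p = P(|U - n1 n2 / 2| >= |U_obs - n1 n2 / 2|).
    """
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    center = n1 * n2 / 2.0
    dev_obs = abs(u_obs - center) - 1e-12
    hits = 0
    total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - center) >= dev_obs:
            hits += 1
        total += 1
    return float(u_obs), hits / total


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact enumeration (tie-aware) when both groups have <= 8 values,
    otherwise the tie-corrected normal approximation with continuity
    correction.  Direction is sign(median(a) - median(b)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("mann_whitney needs nonempty groups")
    direction = _sign(float(np.median(a) - np.median(b)))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(a.size * b.size / 2.0, 1.0, 0)
    if max(a.size, b.size) <= MANN_WHITNEY_EXACT_MAX_N:
        u, p = _mann_whitney_exact(a, b)
        return TestResult(u, p, direction)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), direction)


# ---------------------------------------------------------------------------
# k-group tests
# ---------------------------------------------------------------------------

def _check_groups(groups, min_size):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups")
    for g in groups:
        if g.size < min_size:
            raise InsufficientDataError(f"every group needs >= {min_size} values")
    return groups


def one_way_anova(groups) -> TestResult:
    """One-way fixed-effects ANOVA; F from F(k-1, N-k)."""
    groups = _check_groups(groups, 2)
    k = len(groups)
    N = sum(g.size for g in groups)
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, N - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return TestResult(0.0, 1.0, 0, float(df1))
        return TestResult(math.inf, 0.0, 0, float(df1))
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    return TestResult(float(f), p, 0, float(df1))


@dataclass(frozen=True)
class TukeyPair:
    i: int
    j: int
    statistic: float
    p_value: float
    effect_direction: int


def tukey_hsd(groups) -> list[TukeyPair]:
    """All-pairs Tukey HSD; adjusted p from the studentized range, df N-k."""
    groups = _check_groups(groups, 2)
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        return [TukeyPair(i, j, 0.0, 1.0, 0)
                for i, j in combinations(range(len(groups)), 2)]
    res = sps.tukey_hsd(*groups)
    out = []
    for i, j in combinations(range(len(groups)), 2):
        d = float(groups[i].mean() - groups[j].mean())
        out.append(TukeyPair(i, j, float(res.statistic[i, j]),
                             float(np.clip(res.pvalue[i, j], 0.0, 1.0)), _sign(d)))
    return out


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis H with tie correction; p from chi-square(k-1)."""
    groups = _check_groups(groups, 1)
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        return TestResult(0.0, 1.0, 0, float(len(groups) - 1))
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), float(p), 0, float(len(groups) - 1))


# ---------------------------------------------------------------------------
# Exact count statistics
# ---------------------------------------------------------------------------

def _log_table_prob(table: np.ndarray) -> float:
    """Log probability of a 2xk table under fixed margins (multivariate
    hypergeometric)."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
            - gammaln(n + 1) - gammaln(table + 1).sum())


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test for a 2xk table of counts.

    2x2 tables use the standard hypergeometric rule (sum of probabilities of
    tables at most as probable as the observed one).  Wider tables use the
    Freeman–Halton generalization by full enumeration of tables with the
    observed margins, limited to k <= 5 and total count <= 250.
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] != 2:
        raise InvalidTableError("expected a 2xk table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if np.any(table < 0) or np.any(table != np.rint(table)):
            raise InvalidTableError("counts must be nonnegative integers")
        table = table.astype(np.int64)
    if table.sum() == 0:
        raise InvalidTableError("all margins are zero")
    k = table.shape[1]
    row1 = table[0].sum()
    cols = table.sum(axis=0)
    p1 = table[0, 0] / table[0].sum() if table[0].sum() else 0.0
    p2 = table[1, 0] / table[1].sum() if table[1].sum() else 0.0
    direction = _sign(p1 - p2)

    if k == 2:
        _, p = sps.fisher_exact(table, alternative="two-sided")
        return TestResult(float(table[0, 0]), float(min(p, 1.0)), direction)

    if k > FISHER_MAX_K or table.sum() > FISHER_MAX_TOTAL:
        raise UnsupportedSizeError(
            f"Freeman-Halton enumeration limited to k <= {FISHER_MAX_K} "
            f"and total <= {FISHER_MAX_TOTAL}")

    logp_obs = _log_table_prob(table)
    tol = 1e-7
    total_lp: list[float] = []

    def recurse(col: int, remaining: int, firstrow: list[int]):
        if col == k - 1:
            if remaining <= cols[col]:
                cand = np.array([firstrow + [remaining],
                                 list(cols - np.array(firstrow + [remaining]))])
                total_lp.append(_log_table_prob(cand))
            return
        for v in range(min(remaining, cols[col]) + 1):
            recurse(col + 1, remaining - v, firstrow + [v])

    recurse(0, int(row1), [])
    lps = np.array(total_lp)
    p = float(np.exp(lps[lps <= logp_obs + tol]).sum())
    return TestResult(float(table[0, 0]), min(p, 1.0), direction)


def exact_binomial_ci(successes: int, trials: int, level: float = 0.95) -> ProportionCi:
    """Clopper–Pearson exact binomial confidence interval via Beta quantiles.

    successes = 0 gives lower = 0; successes = trials gives upper = 1.
    """
    if not 0 <= successes <= trials:
        raise InvalidCountsError(f"need 0 <= successes <= trials, got {successes}/{trials}")
    if not 0.0 < level < 1.0:
        raise InvalidCountsError(f"confidence level must be in (0,1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(
        sps.beta.ppf(alpha / 2.0, successes, trials - successes + 1))
    upper = 1.0 if successes == trials else float(
        sps.beta.ppf(1.0 - alpha / 2.0, successes + 1, trials - successes))
    return ProportionCi(successes, trials, level, lower, upper)


# test-choice registry used by the simulation engines
TWO_GROUP_TESTS = {
    "pooled_t": lambda a, b: t_test(a, b, "pooled"),
    "welch_t": lambda a, b: t_test(a, b, "welch"),
    "mann_whitney": mann_whitney,
}

OMNIBUS_TESTS = {
    "anova": one_way_anova,
    "kruskal_wallis": kruskal_wallis,
}
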