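"""Trio-accumulation simulation of a growing two-group study.

Emulates a study that recruits donors in trios (batches of three per group)
and re-runs the group comparison after every batch.  One simulated study
draws all n_max values per group up front ("the population of donors who
will eventually be recruited") and then reveals prefixes of length step,
2*step, ..., n_max — accumulation, never resampling — so the p-value trace
shows how the *same* growing study flips in and out of significance.

A study is classified as "significant" if at least one cumulative look
dipped below alpha (the interim-analysis reading); classification on the
final look only is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import stats
from .errors import (
    InsufficientDataError,
    InvalidBandError,
    InvalidComparisonError,
    InvalidDesignError,
)
from .samplers import GroupSpec, child_rngs, sample_group
from .stats import ProportionCi, TWO_GROUP_TESTS, exact_binomial_ci

logger = logging.getLogger(__name__)

PATTERN_LABELS = ("both_significant", "first_only", "second_only", "never_significant")


@dataclass(frozen=True)
class SignificanceTrace:
    """Per-study record of cumulative and per-trio p-values."""

    n_values: np.ndarray          # cumulative per-group sizes: step, 2*step, ..., n_max
    cumulative_p: np.ndarray
    cumulative_direction: np.ndarray  # sign of mean(A)-mean(B) at each look
    trio_p: np.ndarray            # matched trio-i-vs-trio-i p-values
    alpha: float = 0.05
    test: str = "pooled_t"

    def is_significant(self, rule: str = "any") -> bool:
        """'any': at least one cumulative look below alpha; 'final': last look."""
        if rule == "any":
            return bool(np.any(self.cumulative_p < self.alpha))
        if rule == "final":
            return bool(self.cumulative_p[-1] < self.alpha)
        raise ValueError(f"unknown significance rule {rule!r}")


@dataclass(frozen=True)
class InflectionReport:
    """Sample sizes at which a trace flips state as the study grows."""

    significance_flips: np.ndarray  # n at which (p < alpha) changes
    direction_flips: np.ndarray     # n at which the effect direction changes sign


@dataclass(frozen=True)
class StabilizationResult:
    """Running-mean stabilization over mice tested per donor (MxD)."""

    mxd_values: np.ndarray
    running_mean: np.ndarray
    stabilization_mxd: int
    band: float
    reached: bool


def run_trio_accumulation(spec_a: GroupSpec, spec_b: GroupSpec, n_max: int = 63,
                          step: int = 3, test: str = "pooled_t",
                          alpha: float = 0.05, seed=None) -> SignificanceTrace:
    """Simulate one accumulating study and its p-value trace.

    Draws n_max values per group once, then computes the chosen test on
    (a) each matched trio pair and (b) every cumulative prefix.
    """
    if step < 2:
        raise InvalidDesignError(f"step must be >= 2, got {step}")
    if n_max < step or n_max % step != 0:
        raise InvalidDesignError(f"n_max ({n_max}) must be a positive multiple of step ({step})")
    test_fn = TWO_GROUP_TESTS[test]
    rng_a, rng_b = child_rngs(seed, 2)
    a = sample_group(spec_a, n_max, rng_a)
    b = sample_group(spec_b, n_max, rng_b)

    n_trios = n_max // step
    trio_p = np.empty(n_trios)
    cum_p = np.empty(n_trios)
    cum_dir = np.empty(n_trios, dtype=int)
    for i in range(n_trios):
        lo, hi = i * step, (i + 1) * step
        trio_p[i] = test_fn(a[lo:hi], b[lo:hi]).p_value
        res = test_fn(a[:hi], b[:hi])
        cum_p[i] = res.p_value
        cum_dir[i] = res.effect_direction
    n_values = step * np.arange(1, n_trios + 1)
    return SignificanceTrace(n_values, cum_p, cum_dir, trio_p, alpha, test)


def classify_pattern(trace_ab: SignificanceTrace, trace_ac: SignificanceTrace,
                     rule: str = "any") -> str:
    """Label the joint significance pattern of two traces sharing one referent.

    The four labels (both_significant / first_only / second_only /
    never_significant) partition all outcomes of comparing one group against
    two others across the accumulation.
    """
    if not np.array_equal(trace_ab.n_values, trace_ac.n_values):
        raise InvalidComparisonError("traces were computed on different n grids")
    s1 = trace_ab.is_significant(rule)
    s2 = trace_ac.is_significant(rule)
    if s1 and s2:
        return "both_significant"
    if s1:
        return "first_only"
    if s2:
        return "second_only"
    return "never_significant"


def cumulative_significance_probability(traces, rule: str = "any",
                                        level: float = 0.95) -> tuple[float, ProportionCi]:
    """Fraction of simulated studies with >= 1 significant look, with exact CI."""
    traces = list(traces)
    if not traces:
        raise InsufficientDataError("need at least one trace")
    k = sum(t.is_significant(rule) for t in traces)
    ci = exact_binomial_ci(k, len(traces), level)
    return k / len(traces), ci


def detect_erratic_inflections(trace: SignificanceTrace) -> InflectionReport:
    """Sample sizes at which significance status or effect direction flips."""
    sig = trace.cumulative_p < trace.alpha
    flips = np.flatnonzero(sig[1:] != sig[:-1]) + 1
    d = trace.cumulative_direction
    dir_flips = np.flatnonzero(d[1:] != d[:-1]) + 1
    return InflectionReport(trace.n_values[flips], trace.n_values[dir_flips])


def trace_linearity(trace: SignificanceTrace) -> float:
    """R-squared of the OLS fit of cumulative p against n.

    A perfectly linear drift of the p-value with sample size gives 1; a
    constant trace is defined as 0.
    """
    if trace.n_values.size < 3:
        raise InsufficientDataError("need >= 3 prefixes for a linearity fit")
    x = trace.n_values.astype(float)
    y = trace.cumulative_p
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        return 0.0
    sxx = float(((x - x.mean()) ** 2).sum())
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    ssr = sxy ** 2 / sxx
    return min(max(ssr / sst, 0.0), 1.0)


def mxd_stabilization(spec: GroupSpec, mxd_max: int = 15, band: float = 1.0,
                      seed=None) -> StabilizationResult:
    """Running-mean stabilization as mice per donor (MxD) increases.

    Simulates testing one donor's sample in 1..mxd_max mice and reports the
    smallest MxD beyond which every running mean stays within +/- band
    (outcome units) of the final mean.  ``reached`` is False when only the
    final point itself satisfies the band.
    """
    if band <= 0:
        raise InvalidBandError(f"band must be > 0, got {band}")
    if mxd_max < 2:
        raise InvalidDesignError(f"mxd_max must be >= 2, got {mxd_max}")
    x = sample_group(spec, mxd_max, seed)
    mxd = np.arange(1, mxd_max + 1)
    running = np.cumsum(x) / mxd
    within = np.abs(running - running[-1]) <= band
    m = mxd_max
    for i in range(mxd_max - 1, -1, -1):
        if within[i]:
            m = i + 1
        else:
            break
    return StabilizationResult(mxd, running, m, band, reached=m < mxd_max)
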