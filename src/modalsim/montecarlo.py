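"""Monte Carlo adjusted significance.

"How often would this experiment have been significant if we could rerun
it?"  Each simulation draws fresh groups from the generative specs, runs
the chosen test, and the fraction of significant simulations — with its
exact binomial confidence interval — is the Monte Carlo adjusted p-value
the engines report.  Direction reversals (simulations whose observed mean
difference opposes the configured true difference) are tallied because a
repeated experiment can be "significant in the wrong direction".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidCountError, InsufficientDataError
from .samplers import GroupSpec, child_rngs, mcmc_sample, sample_categorical_uniform, sample_group, McmcConfig
from .stats import (
    OMNIBUS_TESTS,
    ProportionCi,
    TWO_GROUP_TESTS,
    TestResult,
    exact_binomial_ci,
    fisher_exact,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class McSummary:
    n_sims: int
    frac_significant: float
    ci: ProportionCi
    mean_difference: float
    n_direction_reversals: int
    per_sim_p: np.ndarray | None = None


@dataclass(frozen=True)
class CategoricalNullResult:
    n_iterations: int
    n_significant: int
    expected_false_rate: float
    per_iteration_p: np.ndarray
    # Fisher comparison of observed false discoveries against the count
    # expected at alpha in a reference batch of 100 iterations
    fisher_p: float
    reference: tuple[int, int]


def mc_significance_fraction(spec_a: GroupSpec, spec_b: GroupSpec,
                             n_per_group: int, test: str = "pooled_t",
                             alpha: float = 0.05, n_sims: int = 100_000,
                             seed=None, keep_per_sim_p: bool = False) -> McSummary:
    """Fraction of simulated two-group experiments reaching p < alpha.

    Each simulation draws fresh groups of ``n_per_group`` from each spec and
    applies the test; the summary carries a Clopper-Pearson 95% CI for the
    significant fraction, the average observed mean difference, and the
    count of simulations whose difference sign opposed the true one.
    """
    if n_sims < 1:
        raise InvalidCountError("n_sims must be >= 1")
    if n_per_group < 2:
        raise InvalidCountError("n_per_group must be >= 2")
    test_fn = TWO_GROUP_TESTS[test]
    true_sign = np.sign(spec_a.true_mean - spec_b.true_mean)
    logger.info("mc_significance_fraction: n=%d sims=%d test=%s", n_per_group, n_sims, test)

    rngs = child_rngs(seed, n_sims)
    n_sig = 0
    n_rev = 0
    diff_sum = 0.0
    pvals = np.empty(n_sims) if keep_per_sim_p else None
    for i, rng in enumerate(rngs):
        a = sample_group(spec_a, n_per_group, rng)
        b = sample_group(spec_b, n_per_group, rng)
        res = test_fn(a, b)
        if res.p_value < alpha:
            n_sig += 1
        d = a.mean() - b.mean()
        diff_sum += d
        if true_sign != 0 and np.sign(d) == -true_sign:
            n_rev += 1
        if pvals is not None:
            pvals[i] = res.p_value
    ci = exact_binomial_ci(n_sig, n_sims)
    return McSummary(n_sims, n_sig / n_sims, ci, diff_sum / n_sims, n_rev, pvals)


def mc_anova_family(specs, n_per_group: int, alpha: float = 0.05,
                    n_sims: int = 10_000, seed=None,
                    test: str = "anova", keep_per_sim_p: bool = False) -> McSummary:
    """Fraction of simulated k-group experiments with omnibus p < alpha."""
    specs = list(specs)
    if len(specs) < 2:
        raise InsufficientDataError("need >= 2 group specs")
    if n_sims < 1:
        raise InvalidCountError("n_sims must be >= 1")
    test_fn = OMNIBUS_TESTS[test]
    logger.info("mc_anova_family: k=%d n=%d sims=%d", len(specs), n_per_group, n_sims)

    true_means = [s.true_mean for s in specs]
    true_spread = max(true_means) - min(true_means)
    rngs = child_rngs(seed, n_sims)
    n_sig = 0
    spread_sum = 0.0
    pvals = np.empty(n_sims) if keep_per_sim_p else None
    for i, rng in enumerate(rngs):
        groups = [sample_group(s, n_per_group, rng) for s in specs]
        res = test_fn(groups)
        if res.p_value < alpha:
            n_sig += 1
        means = [g.mean() for g in groups]
        spread_sum += max(means) - min(means)
        if pvals is not None:
            pvals[i] = res.p_value
    ci = exact_binomial_ci(n_sig, n_sims)
    # mean_difference reports the average observed max-min group spread;
    # direction reversals are undefined for an omnibus test
    del true_spread
    return McSummary(n_sims, n_sig / n_sims, ci, spread_sum / n_sims, 0, pvals)


def categorical_null_experiment(k_groups: int = 5, k_low: int = 1, k_high: int = 6,
                                n_per_group: int = 1000, test: str = "anova",
                                alpha: float = 0.05, n_iterations: int = 50,
                                seed=None) -> CategoricalNullResult:
    """Null categorical experiment: k identical integer-category groups.

    Every iteration draws ``k_groups`` independent uniform-integer groups
    (no true differences) and records whether the omnibus test flags at
    least one group as different — a pure false discovery.  The observed
    false-discovery count is compared by Fisher exact test against the
    count expected at alpha in a reference batch of 100 iterations.
    """
    if k_groups < 2:
        raise InsufficientDataError("need >= 2 groups")
    if n_iterations < 1:
        raise InvalidCountError("n_iterations must be >= 1")
    test_fn = OMNIBUS_TESTS[test]
    rngs = child_rngs(seed, n_iterations)
    pvals = np.empty(n_iterations)
    for i, rng in enumerate(rngs):
        groups = [sample_categorical_uniform(k_low, k_high, n_per_group, rng)
                  for _ in range(k_groups)]
        pvals[i] = test_fn(groups).p_value
    n_sig = int(np.sum(pvals < alpha))
    ref_trials = 100
    ref_sig = int(round(alpha * ref_trials))
    table = [[n_sig, n_iterations - n_sig], [ref_sig, ref_trials - ref_sig]]
    fp = fisher_exact(table).p_value
    logger.info("categorical_null_experiment: %d/%d significant (expected rate %.3f)",
                n_sig, n_iterations, alpha)
    return CategoricalNullResult(n_iterations, n_sig, alpha, pvals, fp,
                                 (ref_sig, ref_trials))


@dataclass(frozen=True)
class McmcComparison:
    """Two multimodal groups drawn by MCMC and compared at one N."""

    n_per_group: int
    test_result: TestResult
    dip_a: "object"   # modality.DipResult
    dip_b: "object"


def mcmc_group_comparison(target_a, target_b, n_per_group: int,
                          test: str = "pooled_t", mcmc: McmcConfig | None = None,
                          seed=None, n_boot: int = 500) -> McmcComparison:
    """Draw two groups from multimodal targets by Metropolis–Hastings and
    compare them, reporting the location test and each group's dip test."""
    from .modality import dip_test  # local import to avoid a cycle

    ss = np.random.SeedSequence(seed).spawn(4)
    base = mcmc or McmcConfig()
    cfg_a = McmcConfig(base.proposal_scale, base.burn_in, base.thin,
                       seed=int(ss[0].generate_state(1)[0] % (2**31)))
    cfg_b = McmcConfig(base.proposal_scale, base.burn_in, base.thin,
                       seed=int(ss[1].generate_state(1)[0] % (2**31)))
    a = mcmc_sample(target_a, n_per_group, cfg_a)
    b = mcmc_sample(target_b, n_per_group, cfg_b)
    res = TWO_GROUP_TESTS[test](a, b)
    dip_a = dip_test(a, n_boot=n_boot, seed=ss[2])
    dip_b = dip_test(b, n_boot=n_boot, seed=ss[3])
    return McmcComparison(n_per_group, res, dip_a, dip_b)
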