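"""Hypothesis tests and exact intervals against independent oracles."""

import numpy as np
import pytest
from itertools import combinations

from scipy import stats as sps

from modalsim import (
    exact_binomial_ci,
    fisher_exact,
    kruskal_wallis,
    mann_whitney,
    one_way_anova,
    t_test,
    tukey_hsd,
)
from modalsim.errors import (
    InsufficientDataError,
    InvalidCountsError,
    InvalidTableError,
    UnsupportedSizeError,
)


class TestTTest:
    def test_identical_groups(self):
        r = t_test([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0 and r.p_value == 1 and r.effect_direction == 0

    def test_separated_groups(self):
        r = t_test([0, 0, 1, 1], [10, 10, 11, 11], "pooled")
        assert r.p_value < 0.001 and r.effect_direction == -1 and r.df == 6

    @pytest.mark.parametrize("variant", ["pooled", "welch"])
    def test_matches_scipy(self, variant):
        rng = np.random.default_rng(0)
        for _ in range(30):
            a = rng.normal(0, 1, rng.integers(3, 40))
            b = rng.normal(rng.normal(), rng.uniform(0.5, 3), rng.integers(3, 40))
            r = t_test(a, b, variant)
            ref = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
            assert r.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert r.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_agrees_with_permutation_oracle(self):
        """Pooled-t p matches a label-permutation p within Monte Carlo error."""
        n_perm = 4000
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.8, 4, 63)
            b = rng.normal(0, 4, 63)
            p_t = t_test(a, b, "pooled").p_value
            pooled = np.concatenate([a, b])
            obs = abs(a.mean() - b.mean())
            prng = np.random.default_rng(1000 + seed)
            hits = 0
            for _ in range(n_perm):
                perm = prng.permutation(pooled)
                hits += abs(perm[:63].mean() - perm[63:].mean()) >= obs
            p_perm = hits / n_perm
            tol = 4 * np.sqrt(max(p_perm, 0.01) * (1 - max(p_perm, 0.01)) / n_perm) + 0.01
            assert abs(p_t - p_perm) < tol, f"seed {seed}: {p_t} vs {p_perm}"

    def test_constant_unequal_groups(self):
        r = t_test([1, 1, 1], [2, 2, 2])
        assert r.p_value == 0.0 and r.effect_direction == -1

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            t_test([1], [1, 2])


class TestMannWhitney:
    def test_identical_groups(self):
        assert mann_whitney([1, 2, 3, 4], [1, 2, 3, 4]).p_value == 1

    def test_fully_separated_exact(self):
        # most extreme of the C(6,3)=20 rank splits, both tails: p = 2/20
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.p_value == pytest.approx(0.1)
        assert r.effect_direction == -1

    def test_ties_match_independent_enumeration(self):
        """Tie-heavy exact p equals an enumeration using the pairwise-count
        definition of U (a different computation than rank sums)."""
        a, b = np.array([1.0, 1, 2]), np.array([1.0, 2, 2])

        def u_pairwise(x, y):
            return sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)

        pooled = np.concatenate([a, b])
        center = a.size * b.size / 2
        dev_obs = abs(u_pairwise(a, b) - center) - 1e-12
        hits = total = 0
        for idx in combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(idx)] = True
            u = u_pairwise(pooled[mask], pooled[~mask])
            hits += abs(u - center) >= dev_obs
            total += 1
        assert mann_whitney(a, b).p_value == pytest.approx(hits / total)

    def test_large_sample_uses_tie_corrected_normal(self):
        rng = np.random.default_rng(4)
        a = rng.integers(1, 5, 40).astype(float)
        b = rng.integers(1, 5, 40).astype(float)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert mann_whitney(a, b).p_value == pytest.approx(ref.pvalue)

    def test_empty_group(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney([], [1, 2])


class TestAnovaFamily:
    def test_identical_groups(self):
        r = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert r.statistic == 0 and r.p_value == 1

    def test_zero_within_variance(self):
        r = one_way_anova([[0, 0], [0, 0], [5, 5]])
        assert r.p_value < 0.001

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            groups = [rng.normal(rng.normal(), 1, rng.integers(3, 20)) for _ in range(4)]
            r = one_way_anova(groups)
            ref = sps.f_oneway(*groups)
            assert r.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert r.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_null_p_is_uniform(self):
        """Under H0 the ANOVA p-value is U(0,1) (KS check at 1%)."""
        rng = np.random.default_rng(2)
        ps = [one_way_anova([rng.normal(0, 1, 10) for _ in range(3)]).p_value
              for _ in range(2000)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_tukey_identical_groups(self):
        for pair in tukey_hsd([[1, 2, 3], [1, 2, 3], [1, 2, 3]]):
            assert pair.p_value == 1

    def test_tukey_two_groups_equals_pooled_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        tk = tukey_hsd([a, b])[0]
        assert tk.p_value == pytest.approx(t_test(a, b, "pooled").p_value, abs=1e-6)

    def test_tukey_flags_only_the_shifted_group(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(6, 1, 15)]
        pairs = {(p.i, p.j): p.p_value for p in tukey_hsd(groups)}
        assert pairs[(0, 1)] > 0.05
        assert pairs[(0, 2)] < 0.05 and pairs[(1, 2)] < 0.05

    def test_kruskal_identical(self):
        assert kruskal_wallis([[2, 2], [2, 2]]).p_value == 1

    def test_kruskal_closed_form(self):
        # tie-free ranks 1..6 split consecutively: H = 4.571
        r = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert r.statistic == pytest.approx(32 / 7, rel=1e-6)
        assert r.p_value == pytest.approx(float(sps.chi2.sf(32 / 7, 2)))

    def test_kruskal_tie_correction_formula(self):
        """H on tied integer data equals the textbook tie-corrected formula."""
        rng = np.random.default_rng(5)
        groups = [rng.integers(1, 4, 3).astype(float) for _ in range(3)]
        allv = np.concatenate(groups)
        ranks = sps.rankdata(allv)
        N = allv.size
        start = 0
        h = 0.0
        for g in groups:
            r = ranks[start:start + g.size]
            h += r.sum() ** 2 / g.size
            start += g.size
        h = 12 / (N * (N + 1)) * h - 3 * (N + 1)
        _, counts = np.unique(allv, return_counts=True)
        h /= 1 - np.sum(counts ** 3 - counts) / (N ** 3 - N)
        assert kruskal_wallis(groups).statistic == pytest.approx(h, rel=1e-10)


class TestFisherExact:
    def test_printed_false_discovery_table(self):
        # 3 significant of 50 iterations vs the 5 expected per 100
        assert fisher_exact([[3, 47], [5, 95]]).p_value == pytest.approx(1.0)

    def test_identical_rows(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_perfect_split_enumeration(self):
        assert fisher_exact([[5, 0], [0, 5]]).p_value == pytest.approx(2 / 252)

    def test_freeman_halton_matches_r(self):
        """2x4 false-discovery table; reference value from R's fisher.test."""
        r = fisher_exact([[3, 2, 4, 1], [47, 38, 36, 39]])
        assert r.p_value == pytest.approx(0.6222, abs=2e-3)

    def test_freeman_halton_reduces_to_2x2_rule(self):
        t = np.array([[4, 1], [2, 7]])
        p22 = fisher_exact(t).p_value
        ref = sps.fisher_exact(t)[1]
        assert p22 == pytest.approx(ref)

    def test_errors(self):
        with pytest.raises(InvalidTableError):
            fisher_exact([[-1, 2], [3, 4]])
        with pytest.raises(UnsupportedSizeError):
            fisher_exact([[100, 100, 100], [100, 100, 100]])


class TestClopperPearson:
    @pytest.mark.parametrize("k, n, lo, hi", [
        (1, 38, 0.1, 13.8),
        (4, 38, 2.9, 24.8),
        (25, 38, 48.6, 80.4),
    ])
    def test_printed_intervals(self, k, n, lo, hi):
        ci = exact_binomial_ci(k, n, 0.95)
        assert round(ci.lower * 100, 1) == lo
        assert round(ci.upper * 100, 1) == hi

    def test_boundary_conventions(self):
        assert exact_binomial_ci(0, 38).lower == 0
        assert exact_binomial_ci(38, 38).upper == 1

    def test_coverage_is_at_least_nominal(self):
        """Exact coverage by binomial enumeration at n = 38 over a p grid."""
        n = 38
        ks = np.arange(n + 1)
        cis = [exact_binomial_ci(int(k), n, 0.95) for k in ks]
        for p in np.arange(0.05, 0.96, 0.05):
            pmf = sps.binom.pmf(ks, n, p)
            covered = [ci.lower <= p <= ci.upper for ci in cis]
            assert np.sum(pmf[covered]) >= 0.95 - 1e-12

    def test_invalid_counts(self):
        with pytest.raises(InvalidCountsError):
            exact_binomial_ci(5, 3)


@pytest.mark.parametrize("test_fn", [
    lambda a, b: t_test(a, b, "pooled"),
    lambda a, b: t_test(a, b, "welch"),
    mann_whitney,
])
def test_swap_symmetry(test_fn):
    """Swapping the groups flips the direction and preserves the p-value."""
    rng = np.random.default_rng(8)
    for _ in range(20):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.7, 1.5, 9)
        r1, r2 = test_fn(a, b), test_fn(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        assert r1.effect_direction == -r2.effect_direction
        assert 0 <= r1.p_value <= 1
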