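"""Nonparametric cohort statistics against independent oracles."""

import itertools
import time

import numpy as np
import pytest
from scipy import stats as sps

from prmstrain.errors import InputError
from prmstrain.phantom import CohortSpec, generate_cohort_ratios
from prmstrain.stats import compare_cohorts, mann_whitney_u, shapiro_wilk, welch_t


class TestMannWhitney:
    def test_separated_triples_exact(self):
        u, p, method = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)
        assert method == "exact_enumeration"

    def test_complete_tie(self):
        u, p, _ = mann_whitney_u([5.0], [5.0])
        assert u == 0.5
        assert p == 1.0

    def test_symmetry(self, rng):
        a, b = rng.normal(size=6), rng.normal(1.0, size=7)
        assert mann_whitney_u(a, b)[:2] == mann_whitney_u(b, a)[:2]

    @pytest.mark.parametrize("n_a,n_b", [(2, 2), (3, 4), (5, 5), (4, 8), (6, 6)])
    def test_matches_scipy_exact_oracle(self, n_a, n_b, rng):
        # tie-free data, pooled n <= 12: scipy's exact distribution is the oracle
        for _ in range(5):
            a = rng.normal(size=n_a)
            b = rng.normal(0.5, size=n_b)
            u, p, method = mann_whitney_u(a, b)
            assert method == "exact_enumeration"
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert min(ref.statistic, n_a * n_b - ref.statistic) == pytest.approx(u)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_exact_agrees_with_brute_force_under_ties(self, rng):
        # ties handled by enumerating the observed multiset with midranks
        a = [1.0, 2.0, 2.0, 3.0]
        b = [2.0, 3.0, 4.0]
        u_obs, p, method = mann_whitney_u(a, b)
        assert method == "exact_enumeration"
        pooled = np.array(a + b)
        ranks = sps.rankdata(pooled)
        n_a, n_b = len(a), len(b)
        hits = total = 0
        for comb in itertools.combinations(range(len(pooled)), n_a):
            ua = ranks[list(comb)].sum() - n_a * (n_a + 1) / 2
            if min(ua, n_a * n_b - ua) <= u_obs + 1e-9:
                hits += 1
            total += 1
        assert p == pytest.approx(hits / total)

    def test_eight_vs_ten_uses_exact_enumeration_quickly(self, rng):
        a, b = rng.normal(size=8), rng.normal(1.0, size=10)
        t0 = time.perf_counter()
        _, _, method = mann_whitney_u(a, b)
        assert method == "exact_enumeration"
        assert time.perf_counter() - t0 < 1.0

    def test_large_groups_use_normal_approximation(self, rng):
        a, b = rng.normal(size=60), rng.normal(0.2, size=60)
        u, p, method = mann_whitney_u(a, b)
        assert method == "normal_approximation"
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=0.01)

    def test_p_decreases_with_shift(self, rng):
        a = rng.normal(size=8)
        base = rng.normal(size=10)
        ps = [mann_whitney_u(a, base + shift)[1] for shift in (0.5, 1.5, 3.0, 6.0)]
        assert all(x >= y - 1e-12 for x, y in zip(ps, ps[1:]))

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            mann_whitney_u([], [1.0])


class TestShapiroWilk:
    def test_null_calibration_and_lognormal_power(self):
        normal_ok = lognormal_hit = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            if shapiro_wilk(r.normal(size=200))[1] > 0.05:
                normal_ok += 1
            if shapiro_wilk(np.exp(r.normal(0, 1.2, size=50)))[1] < 0.05:
                lognormal_hit += 1
        assert normal_ok >= 90
        assert lognormal_hit >= 95

    def test_affine_invariance(self, rng):
        x = rng.normal(size=30)
        w1, _ = shapiro_wilk(x)
        w2, _ = shapiro_wilk(3.0 * x - 7.0)
        assert w1 == pytest.approx(w2, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InputError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(InputError):
            shapiro_wilk([2.0] * 10)


class TestWelchT:
    def test_identical_groups(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # equal variances 1, means 2 vs 3: t = -1 / sqrt(2/3)
        t, _ = welch_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert t == pytest.approx(-1.0 / np.sqrt(2.0 / 3.0))

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=9), rng.normal(0.7, size=11)
        ta, pa = welch_t(a, b)
        tb, pb = welch_t(b, a)
        assert ta == pytest.approx(-tb)
        assert pa == pytest.approx(pb)


class TestCompareCohorts:
    def test_reference_cohort_sizes_use_exact_method(self):
        a, b = generate_cohort_ratios(CohortSpec(seed=7))
        comp = compare_cohorts(a, b)
        assert comp.method == "exact_enumeration"
        assert len(comp.ratios_a) == 8 and len(comp.ratios_b) == 10
        assert 0.0 <= comp.p_value <= 1.0
        assert comp.to_dict()["five_number_summaries"]["a"]["min"] <= comp.medians[0]

    def test_large_shift_is_significant(self, rng):
        a = rng.normal(0.0, 0.1, size=8)
        b = rng.normal(5.0, 0.1, size=10)
        assert compare_cohorts(a, b).significant
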