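"""Statistical suite: screening, exact Wilcoxon, Kruskal–Wallis, Dunn–Sidak."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from radphantom.stats import (
    StatsError,
    dunn_sidak,
    kruskal_wallis,
    levene,
    one_sample_t,
    shapiro_wilk,
    sidak_adjust,
    wilcoxon_signed_rank,
)


class TestShapiroWilk:
    def test_published_normality_calls(self, errors_by_system):
        """Shapiro–Wilk p-values match the printed normality column: the
        one-shot system rejects, every other system does not."""
        assert shapiro_wilk(errors_by_system["Eagle Eye"]).p_value == \
            pytest.approx(0.358, abs=0.02)
        assert shapiro_wilk(errors_by_system["DSI-DRP"]).p_value < 0.05

    def test_outlier_mixture_rejects_harder_than_gaussian(self, rng):
        gauss = rng.normal(size=40)
        mixture = np.concatenate([rng.normal(size=36), [15, -18, 22, -16]])
        assert (shapiro_wilk(mixture).p_value
                < shapiro_wilk(gauss).p_value / 100)

    def test_constant_sample_rejected(self):
        with pytest.raises(StatsError):
            shapiro_wilk([1.0] * 10)


class TestLevene:
    def test_published_homogeneity_p(self, errors_by_method):
        """Mean-centered Levene reproduces the printed p = 0.4988 (4 dp) —
        the center convention this pins down."""
        res = levene(errors_by_method.values(), center="mean")
        assert res.p_value == pytest.approx(0.4988, abs=5e-5)

    def test_identical_groups_give_zero_f(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = levene([g, list(g)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_power_against_doubled_variance(self, rng):
        """Variance-doubled pairs reject at the 5% level in at least 80%
        of 100 seeded replicates (at n = 100 per group, where the test's
        measured power clears that bar; n = 50 gives only ~58%)."""
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, 100)
            b = rng.normal(0, np.sqrt(2.0), 100)
            hits += levene([a, b]).p_value < 0.05
        assert hits >= 80


class TestOneSampleT:
    def test_published_zero_bias_p_values(self, errors_by_system):
        assert one_sample_t(errors_by_system["GC85A"]).p_value == \
            pytest.approx(0.001, abs=5e-4)
        assert one_sample_t(errors_by_system["Eagle Eye"]).p_value == \
            pytest.approx(0.545, abs=0.005)

    def test_symmetric_sample_gives_t_zero(self):
        res = one_sample_t([-3.0, -1.0, 1.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)


class TestWilcoxonExact:
    def test_all_negative_n9_gives_2_over_512(self, errors_by_system):
        """An all-one-signed sample of n = 9 has the exact two-sided
        p = 2/512, matching the printed 0.004 rows."""
        res = wilcoxon_signed_rank(errors_by_system["UDR780IPRO3F"])
        assert res.p_value == pytest.approx(2 / 512)
        assert res.p_value == pytest.approx(0.004, abs=5e-4)

    def test_single_positive_observation(self):
        assert wilcoxon_signed_rank([1.0]).p_value == 1.0

    def test_one_positive_among_nine(self, errors_by_system):
        """The rotational system with one positive error: W+ = 4, lower
        tail 7/512, two-sided 14/512 ~ 0.0273 (printed 0.027)."""
        res = wilcoxon_signed_rank(errors_by_system["DRX-Compass"])
        assert res.statistic == 4.0
        assert res.p_value == pytest.approx(14 / 512)

    @pytest.mark.parametrize("n", [1, 5, 9, 14, 25])
    def test_closed_form_for_one_signed_samples(self, n):
        """p = 2 x 2^-n for any all-positive sample without ties."""
        sample = np.arange(1, n + 1) * 1.37
        assert wilcoxon_signed_rank(sample).p_value == pytest.approx(
            2.0 * 2.0**-n)

    @pytest.mark.parametrize("seed", [3, 17, 29])
    def test_matches_brute_force_enumeration(self, seed):
        """The generating-function distribution equals explicit 2^n sign
        enumeration, midranks and all."""
        rng = np.random.default_rng(seed)
        x = np.round(rng.normal(0.4, 1.0, 10), 1)  # rounding makes ties
        x = x[x != 0]
        n = len(x)
        ranks = sps.rankdata(np.abs(x))
        w_obs = ranks[x > 0].sum()
        lower = upper = 0
        for signs in itertools.product([0, 1], repeat=n):
            w = sum(r for s, r in zip(signs, ranks) if s)
            lower += w <= w_obs + 1e-9
            upper += w >= w_obs - 1e-9
        want = min(1.0, 2 * min(lower, upper) / 2**n)
        assert wilcoxon_signed_rank(x).p_value == pytest.approx(want)

    def test_matches_scipy_exact_on_tie_free_data(self, rng):
        x = rng.normal(0.3, 1.0, 12)
        ours = wilcoxon_signed_rank(x).p_value
        assert ours == pytest.approx(sps.wilcoxon(x, method="exact").pvalue)

    def test_all_zeros_rejected(self):
        with pytest.raises(StatsError):
            wilcoxon_signed_rank([0.0, 0.0])


class TestKruskalWallis:
    def test_published_omnibus(self, errors_by_method):
        """H(2) = 15.86 and epsilon^2 = (H - k + 1)/(N - k) = 0.272 on the
        three method groups (n = 18/27/9)."""
        om = kruskal_wallis(errors_by_method)
        assert om.H == pytest.approx(15.86, abs=0.005)
        assert om.df == 2
        assert om.p_value < 0.001
        assert om.epsilon_sq == pytest.approx(0.272, abs=5e-4)

    def test_matches_scipy(self, errors_by_method):
        H_scipy, p_scipy = sps.kruskal(*errors_by_method.values())
        om = kruskal_wallis(errors_by_method)
        assert om.H == pytest.approx(H_scipy, rel=1e-12)
        assert om.p_value == pytest.approx(p_scipy, rel=1e-9)

    def test_identical_groups_give_zero_h(self):
        g = [1.0, 2.0, 3.0]
        om = kruskal_wallis([g, list(g), list(g)])
        assert om.H == pytest.approx(0.0, abs=1e-9)

    def test_two_groups_reduce_to_rank_sum_z_squared(self):
        """For k = 2, H equals z^2 from the normal-approximation rank-sum
        test — checked against a brute-force rank computation on 5 + 5."""
        a = [1.2, 3.4, 0.2, 5.5, 2.2]
        b = [4.1, 6.7, 8.0, 3.9, 7.2]
        ranks = sps.rankdata(np.concatenate([a, b]))
        r1 = ranks[:5].sum()
        n1 = n2 = 5
        mu = n1 * (n1 + n2 + 1) / 2
        sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        z = (r1 - mu) / sigma
        om = kruskal_wallis([a, b])
        assert om.H == pytest.approx(z**2, rel=1e-12)

    def test_h_invariant_under_monotone_transforms(self, errors_by_method):
        om0 = kruskal_wallis(errors_by_method)
        for f in (lambda x: np.exp(x / 10.0), lambda x: x**3,
                  lambda x: np.arctan(x)):
            om = kruskal_wallis({m: f(np.asarray(e))
                                 for m, e in errors_by_method.items()})
            assert om.H == pytest.approx(om0.H, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            kruskal_wallis([[1.0, 2.0], []])


class TestDunnSidak:
    def test_published_pairwise_comparisons(self, errors_by_method):
        """All three printed post hoc rows: MRD, simultaneous 95% CI and
        Sidak-adjusted p."""
        om = kruskal_wallis(errors_by_method)
        comps = {c.pair: c for c in dunn_sidak(om)}
        c = comps[("slot", "rotational")]
        assert c.mrd == pytest.approx(18.74, abs=0.005)
        assert c.se == pytest.approx(4.787, abs=0.001)
        assert c.ci[0] == pytest.approx(7.31, abs=0.005)
        assert c.ci[1] == pytest.approx(30.17, abs=0.005)
        assert c.p_adj == pytest.approx(0.0003, abs=5e-5)
        c = comps[("slot", "one_shot")]
        assert c.mrd == pytest.approx(15.44, abs=0.005)
        assert c.ci == (pytest.approx(0.11, abs=0.005),
                        pytest.approx(30.78, abs=0.005))
        assert c.p_adj == pytest.approx(0.0478, abs=5e-4)
        c = comps[("rotational", "one_shot")]
        assert c.mrd == pytest.approx(-3.30, abs=0.005)
        assert c.p_adj == pytest.approx(0.9291, abs=5e-4)
        assert c.ci[0] < 0 < c.ci[1]

    def test_ci_and_p_are_mutually_consistent(self, errors_by_method):
        """p_adj < alpha exactly when the simultaneous CI excludes zero."""
        om = kruskal_wallis(errors_by_method)
        for c in dunn_sidak(om):
            excludes = c.ci[0] > 0 or c.ci[1] < 0
            assert (c.p_adj < 0.05) == excludes

    def test_identical_groups_have_zero_mrd(self):
        g = list(np.linspace(-2, 2, 8))
        om = kruskal_wallis({"a": g, "b": list(g), "c": [5.0, 6.0, 7.0]})
        c = {x.pair: x for x in dunn_sidak(om)}[("a", "b")]
        assert c.mrd == pytest.approx(0.0, abs=1e-12)
        assert c.p_adj == pytest.approx(1.0)
        assert c.ci[0] == pytest.approx(-c.ci[1])


class TestSidakAdjust:
    def test_identity_at_m_one_and_boundaries(self):
        assert sidak_adjust(0.3, 1) == pytest.approx(0.3, rel=1e-15)
        assert sidak_adjust(0.0, 5) == 0.0
        assert sidak_adjust(1.0, 5) == 1.0

    def test_published_back_computed_value(self):
        assert sidak_adjust(0.01622, 3) == pytest.approx(0.0479, abs=1e-4)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(0, 1), st.integers(1, 20))
    def test_monotone_and_never_below_raw(self, p, m):
        adj = sidak_adjust(p, m)
        assert 0.0 <= adj <= 1.0
        assert adj >= p - 1e-12
        assert sidak_adjust(p, m + 1) >= adj - 1e-12
        assert sidak_adjust(min(1.0, p + 0.05), m) >= adj - 1e-12


def test_epsilon_squared_range_properties(rng):
    """epsilon^2 = (H - k + 1)/(N - k) never exceeds 1 for H <= N - 1, is
    non-negative exactly when H >= k - 1, and is 0 exactly at H = k - 1.
    (Under the null H can fall below k - 1, where the formula goes
    slightly negative — like an adjusted effect size.)"""
    for _ in range(50):
        groups = [rng.normal(0, 1, rng.integers(3, 15)) for _ in range(3)]
        om = kruskal_wallis(groups)
        assert om.H <= om.n_total - 1 + 1e-9
        assert om.epsilon_sq <= 1.0 + 1e-9
        assert (om.epsilon_sq >= 0) == (om.H >= om.k - 1)
    om = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
    assert (om.H - om.k + 1) == pytest.approx((om.n_total - om.k)
                                              * om.epsilon_sq, abs=1e-12)
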