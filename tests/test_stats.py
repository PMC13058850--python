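import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy import stats as sps

from gridglm.stats import (
    StatsError,
    bonferroni_families,
    cohens_d_from_t,
    jzs_bayes_factor,
    one_sample_test,
    p_from_t,
    pearson_ci,
    welch_test,
)


def jzs_bf10_delta_marginal(t, nu, n_eff, r=0.707):
    """Independent oracle: marginalize the noncentral-t likelihood over the
    Cauchy effect-size prior directly (valid for moderate |t|)."""

    def integrand(delta):
        return sps.nct.pdf(t, nu, delta * np.sqrt(n_eff)) * sps.cauchy.pdf(delta, 0, r)

    num, _ = integrate.quad(integrand, -np.inf, np.inf, epsabs=1e-13, epsrel=1e-10,
                            limit=200)
    return num / sps.t.pdf(t, nu)


class TestJzsBayesFactor:
    @pytest.mark.parametrize(
        "t, expected_bf01",
        [(0.728, 7.31), (-0.443, 8.60)],
    )
    def test_published_null_evidence_values(self, t, expected_bf01):
        _, bf01 = jzs_bayes_factor(t, 110)
        assert bf01 == pytest.approx(expected_bf01, abs=0.01)

    def test_published_alternative_evidence_value(self):
        bf10, _ = jzs_bayes_factor(2.383, 110)
        assert bf10 == pytest.approx(1.57, abs=0.01)

    @pytest.mark.parametrize("n", [5, 20, 110])
    def test_null_favored_at_t_zero(self, n):
        bf10, bf01 = jzs_bayes_factor(0.0, n)
        assert bf10 < 1.0 and bf01 > 1.0

    def test_bf01_at_zero_grows_with_n(self):
        values = [jzs_bayes_factor(0.0, n)[1] for n in (5, 20, 80, 320)]
        assert np.all(np.diff(values) > 0)

    def test_monotone_in_absolute_t(self):
        bf = [jzs_bayes_factor(t, 40)[0] for t in np.linspace(0, 6, 25)]
        assert np.all(np.diff(bf) > 0)

    def test_matches_independent_quadrature_oracle(self):
        for t in (-2.0, 0.0, 0.728, 2.383, 4.5):
            for n in (10, 50, 110):
                bf10, _ = jzs_bayes_factor(t, n)
                oracle = jzs_bf10_delta_marginal(t, n - 1, n)
                assert bf10 == pytest.approx(oracle, rel=1e-3)

    def test_two_sample_matches_oracle_and_pingouin(self):
        n1, n2, t = 80, 30, 1.964
        bf10, _ = jzs_bayes_factor(t, n1, n2=n2)
        oracle = jzs_bf10_delta_marginal(t, n1 + n2 - 2, n1 * n2 / (n1 + n2))
        assert bf10 == pytest.approx(oracle, rel=1e-3)
        pingouin = pytest.importorskip("pingouin")
        ref = float(pingouin.bayesfactor_ttest(t, n1, n2, paired=False, r=0.707))
        assert bf10 == pytest.approx(ref, rel=1e-3)


class TestOneSampleTest:
    def test_published_one_sided_p_and_d(self):
        assert round(p_from_t(0.728, 109), 3) == 0.234
        assert round(p_from_t(2.383, 109), 3) == 0.009
        assert round(cohens_d_from_t(0.728, 110), 2) == 0.07

    def test_statistics_on_synthetic_sample(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.3, 1.0, 40)
        res = one_sample_test(x)
        t_ref, p_ref = sps.ttest_1samp(x, 0.0, alternative="greater")
        assert res.t == pytest.approx(float(t_ref))
        assert res.p == pytest.approx(float(p_ref))
        assert res.d == pytest.approx(res.t / np.sqrt(40))
        assert res.bf10 * res.bf01 == pytest.approx(1.0)

    def test_zero_variance_fails(self):
        with pytest.raises(StatsError):
            one_sample_test([1.0, 1.0, 1.0])

    @settings(deadline=None, max_examples=30)
    @given(st.floats(-5, 5), st.integers(3, 200))
    def test_one_sided_p_symmetry(self, t, n):
        p_hi = float(sps.t.sf(t, n - 1))
        p_lo = float(sps.t.sf(-t, n - 1))
        assert p_hi + p_lo == pytest.approx(1.0)

    def test_type_i_error_calibrated(self):
        """Null simulations reject at the nominal 5% rate (10,000 replicates)."""
        rng = np.random.default_rng(12)
        hits = 0
        n_rep = 10_000
        for _ in range(n_rep):
            x = rng.standard_normal(15)
            if one_sample_test(x, compute_bf=False).p < 0.05:
                hits += 1
        assert hits / n_rep == pytest.approx(0.05, abs=0.01)


class TestWelchTest:
    def test_equal_means_give_half_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = welch_test(a, a + 0.0)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(0.5)

    def test_reduces_to_pooled_t_for_balanced_groups(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        res = welch_test(a, b)
        pooled = sps.ttest_ind(a, b, equal_var=True, alternative="greater")
        assert res.t == pytest.approx(float(pooled.statistic), abs=1e-10)

    def test_df_matches_welch_satterthwaite_oracle(self):
        a = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        b = np.array([2.0, 7.0, 1.0, 9.0])
        res = welch_test(a, b)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        assert res.df == pytest.approx(df, rel=1e-12)


class TestBonferroniFamilies:
    def test_family_sizes_set_thresholds(self):
        tests = {"a": 0.02, "b": 0.03, "c": 0.01, "d": 0.2, "e": 0.014, "f": 0.04, "g": 0.04}
        fams = {"a": "primary", "b": "primary",
                "c": "control", "d": "control", "e": "control", "f": "control",
                "g": "solo"}
        out = bonferroni_families(tests, fams)
        assert out["a"] == ("primary", 0.025, True)
        assert out["b"] == ("primary", 0.025, False)
        assert out["c"][1] == pytest.approx(0.0125)
        assert out["e"] == ("control", 0.0125, False)
        assert out["g"] == ("solo", 0.05, True)

    def test_unassigned_test_fails(self):
        with pytest.raises(StatsError, match="orphan"):
            bonferroni_families({"orphan": 0.01}, {})


class TestPearsonCi:
    def test_perfect_correlations_degenerate(self):
        x = np.arange(10.0)
        r, (lo, hi) = pearson_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and lo == hi == r
        r_neg, _ = pearson_ci(x, -x)
        assert r_neg == pytest.approx(-1.0)

    def test_matches_fisher_z_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0, 5.0])
        r, (lo, hi) = pearson_ci(x, y)
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(len(x) - 3)
        assert lo == pytest.approx(np.tanh(z - 1.959963984540054 * se))
        assert hi == pytest.approx(np.tanh(z + 1.959963984540054 * se))

    def test_zero_variance_fails(self):
        with pytest.raises(StatsError):
            pearson_ci(np.ones(5), np.arange(5.0))
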