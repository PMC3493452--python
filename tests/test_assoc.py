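"""LT trend statistic, score-test equivalence, OR conversion, meta-analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ltcond import (
    GenotypeMatrix,
    chisq_df_convert,
    impute_missing_covariates,
    liability_effect_to_or,
    lt_test,
    meta_combine,
    posterior_means,
    trend_statistic,
)
from ltcond.experiments import expected_lt_chisq
from ltcond.simulate import toy_t2d_design
from tests.conftest import make_cohort


def score_test_oracle(g, e):
    """Explicit score statistic: U^2 / Var(U), U = sum g_c * e."""
    gc = g - g.mean()
    u = gc @ e
    var_u = (gc @ gc) * ((e - e.mean()) @ (e - e.mean())) / len(g)
    return u**2 / var_u


class TestTrendStatistic:
    def test_toy_design_expected_statistic(self):
        # plug-in at the exact expected stratum genotype moments
        assert expected_lt_chisq(toy_t2d_design(0.1)) == pytest.approx(30.3, abs=0.1)

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=200)
    def test_score_test_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 80)
        g = rng.integers(0, 3, n).astype(float)
        e = rng.normal(size=n)
        if g.std() == 0 or e.std() == 0:
            return
        stat, _, _, defined = trend_statistic(g, e)
        assert defined
        assert stat == pytest.approx(score_test_oracle(g, e), abs=1e-10, rel=1e-10)

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    @settings(deadline=None, max_examples=50)
    def test_affine_invariance_of_statistic(self, a, b):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, 60).astype(float)
        e = rng.normal(size=60)
        s1, _, _, _ = trend_statistic(g, e)
        s2, _, _, _ = trend_statistic(g, a * e + b)
        assert s2 == pytest.approx(s1, rel=1e-10)

    def test_binary_phenotype_reduces_to_armitage(self, rng):
        # with 0/1 "posterior means" this is the classical trend test; check
        # against the closed-form CATT from the 2x3 table
        g = rng.integers(0, 3, 500).astype(float)
        z = rng.integers(0, 2, 500).astype(float)
        n = np.zeros((2, 3))
        for zi, gi in zip(z.astype(int), g.astype(int)):
            n[zi, gi] += 1
        N = n.sum()
        R = n[1].sum()
        cj = n.sum(axis=0)
        w = np.arange(3.0)
        num = (w * (n[1] - R * cj / N)).sum() ** 2
        den = (R / N) * (1 - R / N) * ((w**2 * cj).sum() - (w * cj).sum() ** 2 / N)
        catt = num / den
        stat, _, _, _ = trend_statistic(g, z)
        assert stat == pytest.approx(catt, rel=1e-10)

    def test_nuisance_residualization_matches_partial_correlation(self, rng):
        n, k = 300, 2
        C = rng.normal(size=(n, k))
        g = rng.integers(0, 3, n).astype(float) + 0.1 * C[:, 0]
        g = np.clip(g, 0, 2)
        e = rng.normal(size=n) + 0.3 * C[:, 1]
        stat, slope, se, _ = trend_statistic(g, e, nuisance=C)
        # oracle: residualize with lstsq independently
        P = np.column_stack([np.ones(n), C])
        rg = g - P @ np.linalg.lstsq(P, g, rcond=None)[0]
        re = e - P @ np.linalg.lstsq(P, e, rcond=None)[0]
        r2 = (rg @ re) ** 2 / ((rg @ rg) * (re @ re))
        assert stat == pytest.approx((n - k - 1) * r2, rel=1e-10)

    def test_monomorphic_snp_flagged_undefined(self):
        stat, _, _, defined = trend_statistic(np.ones(20), np.random.default_rng(0).normal(size=20))
        assert not defined and np.isnan(stat)


class TestLtTest:
    def _pm_and_geno(self, t2d_model, rng, n=400, missing=False):
        bmi = rng.choice([24.0, 35.0], size=n)
        z = rng.integers(0, 2, n)
        cohort = make_cohort(z, bmi[:, None])
        pm = posterior_means(t2d_model, impute_missing_covariates(cohort))
        g = rng.integers(0, 3, (n, 2)).astype(float)
        if missing:
            g[rng.random((n, 2)) < 0.1] = np.nan
        geno = GenotypeMatrix(cohort.sample_ids, ("rs1", "rs2"), g)
        return pm, geno

    def test_results_consistent_statistic_and_p(self, t2d_model, rng):
        pm, geno = self._pm_and_geno(t2d_model, rng)
        for r in lt_test(pm, geno):
            assert r.defined and r.statistic >= 0
            assert r.p_value == pytest.approx(stats.chi2.sf(r.statistic, 1), abs=1e-12)
            assert r.n_used == 400

    def test_missing_policy_complete_vs_mean(self, t2d_model, rng):
        pm, geno = self._pm_and_geno(t2d_model, rng, missing=True)
        comp = lt_test(pm, geno, missing="complete")
        mean = lt_test(pm, geno, missing="mean")
        assert comp[0].n_used < 400
        assert mean[0].n_used == 400
        # with no missing data the two policies coincide
        pm2, geno2 = self._pm_and_geno(t2d_model, rng, missing=False)
        a = lt_test(pm2, geno2, missing="complete")
        b = lt_test(pm2, geno2, missing="mean")
        for ra, rb in zip(a, b):
            assert ra.statistic == pytest.approx(rb.statistic, rel=1e-12)


class TestOrConversion:
    def test_null_effect_gives_unit_or(self, t2d_model):
        assert liability_effect_to_or(t2d_model, 0.0, 0.3, [24.0]) == pytest.approx(1.0)

    def test_toy_low_bmi_or(self, t2d_model):
        orr = liability_effect_to_or(t2d_model, 0.1, 0.5, [24.0])
        assert 1.20 <= orr <= 1.30  # printed 1.25; estimator-dependent

    def test_toy_high_bmi_or_smaller(self, t2d_model):
        lo = liability_effect_to_or(t2d_model, 0.1, 0.5, [24.0])
        hi = liability_effect_to_or(t2d_model, 0.1, 0.5, [35.0])
        assert 1.0 < hi < lo
        assert hi == pytest.approx(1.17, abs=0.03)

    def test_bad_maf_rejected(self, t2d_model):
        with pytest.raises(ValueError):
            liability_effect_to_or(t2d_model, 0.1, 0.0)


class TestChisqConvert:
    def test_identity_and_zero(self):
        assert chisq_df_convert(3.2, 1, 1) == 3.2
        assert chisq_df_convert(0.0, 2, 1) == pytest.approx(0.0, abs=1e-12)

    def test_equal_tail_quantile_at_p005(self):
        v = chisq_df_convert(stats.chi2.isf(0.05, 2), 2, 1)
        assert v == pytest.approx(stats.chi2.isf(0.05, 1), abs=1e-6)
        assert v == pytest.approx(3.841, abs=5e-4)

    def test_tail_probability_preserved(self):
        for x in (0.5, 5.0, 30.0, 200.0):
            y = chisq_df_convert(x, 2, 1)
            assert stats.chi2.sf(y, 1) == pytest.approx(stats.chi2.sf(x, 2), rel=1e-8)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            chisq_df_convert(-1.0, 2, 1)


class TestMetaCombine:
    def test_single_study_identity(self):
        b, s, chi = meta_combine([0.3], [0.1])
        assert (b, s) == (pytest.approx(0.3), pytest.approx(0.1))
        assert chi == pytest.approx(9.0)

    def test_two_identical_studies_halve_variance(self):
        b, s, _ = meta_combine([0.2, 0.2], [0.05, 0.05])
        assert b == pytest.approx(0.2)
        assert s == pytest.approx(0.05 / np.sqrt(2))

    def test_three_studies_match_weighted_mean_oracle(self):
        betas, ses = [0.1, -0.2, 0.35], [0.05, 0.2, 0.11]
        w = 1 / np.asarray(ses) ** 2
        b, s, _ = meta_combine(betas, ses)
        assert b == pytest.approx((w * betas).sum() / w.sum(), abs=1e-12)
        assert s == pytest.approx(np.sqrt(1 / w.sum()), abs=1e-12)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            meta_combine([0.1], [0.0])
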