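"""Simulation engine: dataset generation, vectorized replicates, invariants."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import ltcond
from ltcond import (
    LiabilityModel,
    LogitParams,
    SimDesign,
    Stratum,
    perturb_model,
    run_replicates,
    simulate_logit_dataset,
    simulate_lt_dataset,
)
from ltcond.simulate import toy_t2d_design
from ltcond import _engine


class TestDatasetGeneration:
    def test_determinism_identical_seed(self):
        d = toy_t2d_design(0.1, n_per_stratum=100, seed=5)
        c1, g1 = simulate_lt_dataset(d)
        c2, g2 = simulate_lt_dataset(d)
        assert np.array_equal(g1.dosages, g2.dosages)
        assert np.array_equal(c1.status, c2.status)
        c3, g3 = simulate_lt_dataset(replace(d, seed=6))
        assert not np.array_equal(g1.dosages, g3.dosages)

    def test_null_effect_allele_frequency_is_maf(self):
        d = toy_t2d_design(0.0, n_per_stratum=25_000, seed=1)
        _, geno = simulate_lt_dataset(d)
        af = np.nanmean(geno.dosages) / 2
        assert af == pytest.approx(0.5, abs=0.005)

    def test_case_stratum_allele_frequency_matches_model(self):
        # Cases at BMI 24 should carry the enriched frequency ~0.551
        d = toy_t2d_design(0.1, n_per_stratum=100_000, seed=2)
        cohort, geno = simulate_lt_dataset(d)
        sel = (cohort.status == 1) & (cohort.covariates[:, 0] == 24.0)
        af = geno.dosages[sel, 0].mean() / 2
        se = np.sqrt(0.55 * 0.45 / (2 * sel.sum()))
        assert abs(af - 0.5512) < 4 * se

    def test_random_ascertainment_case_fraction(self, t2d_model):
        d = SimDesign(
            model=t2d_model, gamma=0.0, maf=0.5,
            strata=(Stratum((26.5,), 200_000),),
            ascertainment="random", seed=3,
        )
        cohort, _ = simulate_lt_dataset(d)
        frac = cohort.status.mean()
        expected = stats.norm.sf(1.44)  # ~0.0749
        assert frac == pytest.approx(expected, abs=4 * np.sqrt(expected / 200_000))

    def test_case_control_rejection_reaches_targets(self, t2d_model):
        d = SimDesign(
            model=t2d_model, gamma=0.1, maf=0.5,
            strata=(Stratum((24.0,), 1), Stratum((35.0,), 1)),
            ascertainment="case_control", n_cases=300, n_controls=500, seed=4,
        )
        cohort, geno = simulate_lt_dataset(d)
        assert cohort.status.sum() == 300
        assert (cohort.status == 0).sum() == 500
        assert geno.n_samples == 800

    def test_design_validation(self, t2d_model):
        with pytest.raises(ValueError):
            SimDesign(model=t2d_model, gamma=0.1, maf=1.5,
                      strata=(Stratum((24.0,), 10, 1),))
        with pytest.raises(ValueError):
            SimDesign(model=t2d_model, gamma=0.1, maf=0.5,
                      strata=(Stratum((24.0,), 10),))  # missing status
        with pytest.raises(ValueError):
            SimDesign(model=t2d_model, gamma=0.1, maf=0.5, generator="logit",
                      strata=(Stratum((24.0,), 10, 1),))  # no logit params


class TestLogitGenerator:
    def test_null_logit_gives_half_probability(self, t2d_model):
        d = SimDesign(
            model=t2d_model, gamma=0.0, maf=0.5,
            strata=(Stratum((26.5,), 50_000),),
            generator="logit", logit_params=LogitParams(0.0, 0.0, (0.0,)),
            ascertainment="random", seed=5,
        )
        cohort, _ = simulate_logit_dataset(d)
        assert cohort.status.mean() == pytest.approx(0.5, abs=0.01)

    def test_case_control_sampling_preserves_logistic_slope(self, t2d_model):
        # ORs are invariant under outcome-dependent sampling
        beta = 0.35
        d = SimDesign(
            model=LiabilityModel(affine=-1.0), gamma=0.0, maf=0.3,
            strata=(Stratum((), 1),),
            generator="logit", logit_params=LogitParams(-2.0, beta, ()),
            ascertainment="case_control", n_cases=4000, n_controls=4000, seed=6,
        )
        cohort, geno = simulate_logit_dataset(d)
        res = ltcond.logr_test(cohort.status.astype(float), geno.dosages[:, 0])
        assert res.effect == pytest.approx(beta, abs=3.5 * res.stderr)

    def test_lt_statistic_outperforms_logr_under_matched_logit_model(self, t2d_model):
        # even when the data come from a logit model, informed conditioning
        # on the matched covariate beats plain logistic regression
        lp = LogitParams(intercept=-2.3, genotype_logor=0.2, covariate_logors=(0.15,))
        strata = tuple(
            Stratum((b,), 1500, z) for b in (24.0, 35.0) for z in (1, 0)
        )
        d = SimDesign(
            model=t2d_model, gamma=0.0, maf=0.5, strata=strata,
            generator="logit", logit_params=lp, n_replicates=4000, seed=7,
        )
        s = run_replicates(d, tests=("lt", "logr"), seed=7)
        assert s.mean("lt") > s.mean("logr")


class TestPerturbModel:
    def test_identity(self, t2d_model):
        assert perturb_model(t2d_model) == t2d_model

    def test_doubling_coefficient_steepens_prevalence(self, t2d_model):
        m2 = perturb_model(t2d_model, coefficient_factors=2.0)
        for b in (28.0, 32.0, 35.0):  # above the reference mean
            assert ltcond.predict_prevalence(m2, [b]) > ltcond.predict_prevalence(
                t2d_model, [b]
            )

    def test_nonfinite_factor_rejected(self, t2d_model):
        with pytest.raises(ValueError):
            perturb_model(t2d_model, coefficient_factors=np.inf)


class TestReplicateEngine:
    TESTS = ("lt", "logr", "logr_cov", "g_gxe", "gxe", "logr_sub", "case_only")

    def test_engine_equals_per_sample_statistics(self, t2d_model, rng):
        """One replicate's collapsed-count statistics match the per-sample code."""
        d = toy_t2d_design(0.1)
        probs = _engine.stratum_genotype_probs(d)
        counts = _engine.draw_stratum_counts(probs, [st.count for st in d.strata], 1, rng)
        vals = _engine.stats_from_counts(counts, d, d.model, self.TESTS)
        # expand counts into a per-sample dataset
        g, z, t = [], [], []
        for si, st_ in enumerate(d.strata):
            for gg in range(3):
                k = int(counts[0, si, gg])
                g += [gg] * k
                z += [st_.status] * k
                t += [st_.covariate_values[0]] * k
        g, z, t = np.array(g, float), np.array(z, float), np.array(t, float)
        from tests.conftest import make_cohort

        cohort = make_cohort(z, t[:, None])
        pm = ltcond.posterior_means(t2d_model, ltcond.impute_missing_covariates(cohort))
        ref = {
            "lt": ltcond.trend_statistic(g, pm.posterior_mean)[0],
            "logr": ltcond.logr_test(z, g).statistic,
            "logr_cov": ltcond.logr_test(z, g, covariates=t).statistic,
            "g_gxe": ltcond.g_gxe_test(z, g, t).statistic,
            "gxe": ltcond.gxe_1dof_test(z, g, t).statistic,
            "logr_sub": ltcond.logr_subset_test(z, g, t, 29.5).statistic,
            "case_only": ltcond.case_only_test(t[z == 1], g[z == 1]).statistic,
        }
        for name in self.TESTS:
            assert vals[name][0][0] == pytest.approx(ref[name], abs=1e-6), name

    def test_summary_determinism(self):
        d = toy_t2d_design(0.1, n_replicates=2000)
        s1 = run_replicates(d, tests=("lt", "logr"), seed=42)
        s2 = run_replicates(d, tests=("lt", "logr"), seed=42)
        assert s1.mean("lt") == s2.mean("lt")
        assert s1.tests["logr"].power == s2.tests["logr"].power

    def test_null_mean_and_ks(self):
        d = toy_t2d_design(0.0, n_replicates=20_000)
        s = run_replicates(d, tests=("lt",), seed=9)
        t = s.tests["lt"]
        assert t.mean_chisq == pytest.approx(1.0, abs=3 * t.mc_se)

    def test_power_monotone_in_gamma(self):
        powers = []
        for i, gamma in enumerate((0.0, 0.06, 0.10, 0.15)):
            d = toy_t2d_design(gamma, n_replicates=4000)
            s = run_replicates(d, tests=("lt",), alphas=(1e-4,), seed=100 + i)
            powers.append(s.power("lt", 1e-4))
        assert all(b >= a for a, b in zip(powers, powers[1:]))

    def test_hwe_approx_mode_statistically_indistinguishable(self):
        d = toy_t2d_design(0.1, n_replicates=30_000)
        exact = run_replicates(d, tests=("lt",), seed=11)
        approx = run_replicates(d, tests=("lt",), seed=11, hwe_approx=True)
        se = np.hypot(exact.tests["lt"].mc_se, approx.tests["lt"].mc_se)
        assert abs(exact.mean("lt") - approx.mean("lt")) < 3 * se

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            run_replicates(toy_t2d_design(0.1), tests=("nope",))

    def test_mean_statistic_is_plugin_plus_one(self):
        """E[N r^2] = ncp + 1 for the chi2(1, ncp) statistic; the analytic
        plug-in at expected counts is the noncentrality."""
        from ltcond.experiments import expected_lt_chisq

        d = toy_t2d_design(0.1, n_replicates=50_000)
        s = run_replicates(d, tests=("lt",), seed=13)
        t = s.tests["lt"]
        assert t.mean_chisq == pytest.approx(
            expected_lt_chisq(d) + 1.0, abs=4 * t.mc_se
        )
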