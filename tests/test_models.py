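"""Substitution-model framework: designs, estimators, identities, diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from isosub import models as M, simulate as S
from isosub.exceptions import (ConfigurationError, DegenerateFitError,
                               EstimationError, InputError, RankDeficiencyError)


def fuzz_cohort(seed, n_studies=10, persons_per_study=50):
    rng = np.random.default_rng(seed)
    cfg = S.SimulationConfig(
        n_studies=n_studies, persons_per_study=persons_per_study,
        true_models={"wc": S.TrueModel(
            intercept=float(rng.uniform(50, 80)),
            b_sed=float(rng.normal(0, 0.3)), b_lpa=float(rng.normal(0, 0.3)),
            b_mvpa=float(rng.normal(0, 0.8)), sex_effect=float(rng.normal(0, 3)))},
        study_intercept_sd={"wc": float(rng.uniform(0, 4))},
        residual_sd={"wc": float(rng.uniform(1, 10))},
        seed=int(rng.integers(2**31)))
    return S.simulate_dataset(cfg)


class TestScaleExposures:
    def test_divides_behaviours_and_wear(self):
        df = pd.DataFrame({"sed": [372.0], "lpa": [361.0], "mvpa": [54.0],
                           "wear": [787.0], "wc": [68.6]})
        out = M.scale_exposures(df, 10)
        assert out.loc[0, "sed"] == pytest.approx(37.2)
        assert out.loc[0, "wear"] == pytest.approx(78.7)
        assert out.loc[0, "wc"] == 68.6  # outcomes untouched

    def test_unit_one_is_identity(self):
        df = pd.DataFrame({"sed": [313.0], "lpa": [405.0], "mvpa": [56.0]})
        pd.testing.assert_frame_equal(M.scale_exposures(df, 1), df)

    def test_nonpositive_unit_rejected(self):
        with pytest.raises(ConfigurationError):
            M.scale_exposures(pd.DataFrame({"sed": [1.0]}), 0)


class TestBuildDesign:
    def test_isotemporal_drop_sed_outcome_wc(self, noisy_cohort):
        spec = M.ModelSpec("isotemporal", "wc", dropped="sed", stratum="adolescents")
        _, X, _ = M.build_design(spec, noisy_cohort)
        assert list(X.columns) == ["lpa", "mvpa", "wear", "sex", "const"]

    def test_partition_outcome_sbp_keeps_wc_covariate(self, noisy_cohort):
        df = noisy_cohort.copy()
        df["sbp"] = 100.0 + np.random.default_rng(0).normal(0, 5, len(df))
        spec = M.ModelSpec("partition", "sbp", stratum="children")
        _, X, _ = M.build_design(spec, df)
        assert list(X.columns) == ["sed", "lpa", "mvpa", "sex", "wc", "const"]

    def test_single_mvpa_outcome_wc(self, noisy_cohort):
        spec = M.ModelSpec("single", "wc", exposure="mvpa", stratum="children")
        _, X, _ = M.build_design(spec, noisy_cohort)
        assert list(X.columns) == ["mvpa", "sex", "const"]

    def test_empty_stratum_errors(self, noisy_cohort):
        df = noisy_cohort[noisy_cohort["age_group"] != "older"]
        with pytest.raises(InputError):
            M.build_design(M.ModelSpec("partition", "wc", stratum="older"), df)

    def test_degenerate_collinear_design_names_columns(self, noisy_cohort):
        # constant wear alongside both retained behaviours and the intercept
        # makes the isotemporal design collapse
        df = noisy_cohort.copy()
        scale = 780.0 / (df["sed"] + df["lpa"] + df["mvpa"])
        df["sed"], df["lpa"] = df["sed"] * scale, df["lpa"] * scale
        df["mvpa"] = df["mvpa"] * scale
        df["wear"] = 780.0
        df["dup"] = df["lpa"]
        with pytest.raises(RankDeficiencyError) as err:
            M.build_design(M.ModelSpec("partition", "wc", stratum="adolescents",
                                       covariates=("sex", "dup")), df)
        assert err.value.columns

    def test_spec_validation(self):
        with pytest.raises(ConfigurationError):
            M.ModelSpec("single", "wc")                       # missing exposure
        with pytest.raises(ConfigurationError):
            M.ModelSpec("isotemporal", "wc")                  # missing dropped
        with pytest.raises(ConfigurationError):
            M.ModelSpec("isotemporal", "wc", dropped="sed", include_wear=False)
        with pytest.raises(ConfigurationError):
            M.ModelSpec("partition", "wc", include_wear=True)


class TestFit:
    def test_noiseless_partition_recovers_planted_exactly(self, noiseless_cohort):
        from isosub.reference import WC_ADOLESCENT_PLANTED as b
        for estimator in ("pooled_ols", "random_effects_gls"):
            res = M.fit(M.ModelSpec("partition", "wc", stratum="children",
                                    estimator=estimator, variance="conventional"),
                        noiseless_cohort)
            assert res.beta("sed") == pytest.approx(b["b_sed"], abs=1e-8)
            assert res.beta("mvpa") == pytest.approx(b["b_mvpa"], abs=1e-8)

    def test_isotemporal_equals_partition_contrast(self, noiseless_cohort):
        part = M.fit(M.ModelSpec("partition", "wc", stratum="adolescents"),
                     noiseless_cohort)
        ism = M.fit(M.ModelSpec("isotemporal", "wc", dropped="sed",
                                stratum="adolescents"), noiseless_cohort)
        assert ism.beta("mvpa") == pytest.approx(
            part.beta("mvpa") - part.beta("sed"), abs=1e-10)

    @pytest.mark.parametrize("estimator", ["pooled_ols", "random_effects_gls"])
    def test_reparameterization_identity_fuzzed(self, estimator):
        """ISM coefficient for j with k dropped == b_j - b_k from the
        partition fit, for every pair, on noisy clustered cohorts."""
        for seed in range(5):
            df = fuzz_cohort(seed)
            common = dict(stratum="adolescents", estimator=estimator,
                          variance="conventional")
            part = M.fit(M.ModelSpec("partition", "wc", **common), df)
            for dropped in M.EXPOSURES:
                ism = M.fit(M.ModelSpec("isotemporal", "wc", dropped=dropped,
                                        **common), df)
                for kept in (e for e in M.EXPOSURES if e != dropped):
                    assert abs(ism.beta(kept) -
                               (part.beta(kept) - part.beta(dropped))) < 1e-8

    def test_pooled_ols_matches_statsmodels_oracle(self, noisy_cohort):
        spec = M.ModelSpec("partition", "wc", stratum="adolescents",
                           estimator="pooled_ols", variance="conventional")
        res = M.fit(spec, noisy_cohort)
        scaled = M.scale_exposures(noisy_cohort, 10)
        sub = scaled[scaled["age_group"] == "adolescents"]
        X = sm.add_constant(sub[["sed", "lpa", "mvpa", "sex"]])
        oracle = sm.OLS(sub["wc"], X).fit()
        for term in ("sed", "lpa", "mvpa"):
            assert res.beta(term) == pytest.approx(oracle.params[term], abs=1e-10)
            assert res.params.loc[term, "se"] == pytest.approx(
                oracle.bse[term], abs=1e-10)

    def test_scaling_covariance(self, noisy_cohort):
        """Unit c multiplies exposure coefficients by c; t-statistics and
        p-values are invariant."""
        s10 = M.fit(M.ModelSpec("partition", "wc", stratum="adolescents",
                                exposure_unit=10), noisy_cohort)
        s1 = M.fit(M.ModelSpec("partition", "wc", stratum="adolescents",
                               exposure_unit=1), noisy_cohort)
        for term in M.EXPOSURES:
            assert s10.beta(term) == pytest.approx(10 * s1.beta(term), rel=1e-9)
            t10 = s10.beta(term) / s10.params.loc[term, "se"]
            t1 = s1.beta(term) / s1.params.loc[term, "se"]
            assert t10 == pytest.approx(t1, rel=1e-9)

    def test_single_study_re_reduces_to_ols_and_cluster_errors(self, noisy_cohort):
        one = noisy_cohort[noisy_cohort["study_id"] == "study01"]
        re = M.fit(M.ModelSpec("partition", "wc", stratum="adolescents",
                               estimator="random_effects_gls",
                               variance="conventional"), one)
        ols = M.fit(M.ModelSpec("partition", "wc", stratum="adolescents",
                                estimator="pooled_ols", variance="conventional"), one)
        for term in M.EXPOSURES:
            assert re.beta(term) == pytest.approx(ols.beta(term), abs=1e-10)
        with pytest.raises(EstimationError):
            M.fit(M.ModelSpec("partition", "wc", stratum="adolescents"), one)

    def test_complete_case_counts(self, noisy_cohort):
        df = noisy_cohort.copy().reset_index(drop=True)
        df.loc[df.index[:25], "wc"] = np.nan
        n_expected = int(df[df["age_group"] == "adolescents"]["wc"].notna().sum())
        res = M.fit(M.ModelSpec("partition", "wc", stratum="adolescents"), df)
        assert res.n_obs == n_expected

    def test_constant_outcome_is_degenerate(self, noisy_cohort):
        df = noisy_cohort.copy()
        df["wc"] = 70.0
        with pytest.raises(DegenerateFitError):
            M.fit(M.ModelSpec("partition", "wc", stratum="adolescents"), df)

    def test_cluster_robust_matches_conventional_without_cluster_effects(self):
        """With no study intercepts the two variance estimates agree in
        distribution: their ratio concentrates near 1 at large n."""
        cfg = S.SimulationConfig(n_studies=13, persons_per_study=500,
                                 study_intercept_sd={"wc": 0.0},
                                 residual_sd={"wc": 8.0}, seed=21)
        df = S.simulate_dataset(cfg)
        conv = M.fit(M.ModelSpec("partition", "wc", stratum="adolescents",
                                 estimator="pooled_ols", variance="conventional"), df)
        clus = M.fit(M.ModelSpec("partition", "wc", stratum="adolescents",
                                 estimator="pooled_ols", variance="cluster_robust"), df)
        ratio = clus.params.loc["mvpa", "se"] / conv.params.loc["mvpa", "se"]
        assert 0.6 < ratio < 1.6


class TestRunFramework:
    def test_seven_fits_per_cell(self, noisy_cohort):
        results = M.run_framework(noisy_cohort, ["wc"], ["children"])
        assert len(results) == 7
        classes = [r.spec.model_class for r in results]
        assert classes.count("single") == 3
        assert classes.count("partition") == 1
        assert classes.count("isotemporal") == 3

    def test_three_strata_give_21_fits(self, noisy_cohort):
        results = M.run_framework(noisy_cohort, ["wc"], M.AGE_GROUPS)
        assert len(results) == 21

    def test_wc_not_its_own_covariate(self, noisy_cohort):
        results = M.run_framework(noisy_cohort, ["wc"], ["adolescents"])
        for r in results:
            assert "wc" not in r.params.index


class TestVifTolerance:
    def test_orthogonal_columns_have_unit_vif(self):
        n = 64
        X = pd.DataFrame({"a": np.tile([1.0, -1.0], n // 2),
                          "b": np.repeat([1.0, -1.0], n // 2),
                          "const": 1.0})
        table, mean_vif, min_tol = M.vif_tolerance(X, ["a", "b"])
        assert np.allclose(table["vif"], 1.0)
        assert mean_vif == pytest.approx(1.0) and min_tol == pytest.approx(1.0)

    def test_closed_form_for_correlated_pair(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=4000)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=4000)
        X = pd.DataFrame({"a": a, "b": b, "const": 1.0})
        table, _, _ = M.vif_tolerance(X, ["a", "b"])
        r2 = sm.OLS(a, sm.add_constant(b)).fit().rsquared  # independent route
        assert table.loc["a", "vif"] == pytest.approx(1 / (1 - r2), rel=1e-9)
        assert table.loc["a", "tolerance"] == pytest.approx(1 - r2, rel=1e-9)

    def test_duplicate_columns_rejected(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": x, "const": 1.0})
        with pytest.raises(RankDeficiencyError):
            M.vif_tolerance(X, ["a", "b"])

    def test_low_collinearity_in_realistic_designs(self, noisy_cohort):
        res = M.fit(M.ModelSpec("isotemporal", "wc", dropped="sed",
                                stratum="adolescents"), noisy_cohort)
        assert res.min_tolerance == pytest.approx(1 / res.mean_vif, rel=0.5)
        assert res.mean_vif < 5


class TestInteractionScreen:
    def _null_cohort(self, seed, n_studies=13, persons=30):
        cfg = S.SimulationConfig(
            n_studies=n_studies, persons_per_study=persons,
            study_intercept_sd={"wc": 0.0}, residual_sd={"wc": 6.0}, seed=seed)
        return S.simulate_dataset(cfg)

    def test_size_under_the_null(self):
        """No sex x MVPA effect in the generator: rejection rate ~ alpha."""
        rejections = 0
        reps = 250
        for seed in range(reps):
            df = self._null_cohort(seed)
            p = M.interaction_screen(df, "wc", "adolescents",
                                     estimator="pooled_ols",
                                     variance="conventional")
            rejections += p < 0.05
        rate = rejections / reps
        assert 0.01 < rate < 0.10  # 3 binomial SDs around 0.05

    def test_power_against_a_large_planted_interaction(self):
        hits = 0
        reps = 50
        for seed in range(reps):
            df = self._null_cohort(1000 + seed)
            df = df.copy()
            df["wc"] = df["wc"] + 3.0 * df["sex"] * (df["mvpa"] / 10)  # huge
            p = M.interaction_screen(df, "wc", "adolescents",
                                     estimator="pooled_ols",
                                     variance="conventional")
            hits += p < 0.05
        assert hits >= reps - 1

    def test_single_sex_stratum_errors(self, noisy_cohort):
        df = noisy_cohort.copy()
        df.loc[df["age_group"] == "older", "sex"] = 1
        with pytest.raises(InputError):
            M.interaction_screen(df, "wc", "older")

    def test_constant_outcome_errors(self, noisy_cohort):
        df = noisy_cohort.copy()
        df["wc"] = 70.0
        with pytest.raises(DegenerateFitError):
            M.interaction_screen(df, "wc", "adolescents")


class TestLogSensitivity:
    def _multiplicative_cohort(self, residual=0.0, seed=0):
        cfg = S.SimulationConfig(
            n_studies=6, persons_per_study=80,
            true_models={"insulin": S.TrueModel(intercept=3.6, b_sed=0.01,
                                                b_lpa=-0.002, b_mvpa=-0.08)},
            study_intercept_sd={"insulin": 0.0},
            residual_sd={"insulin": residual},
            lognormal_outcomes=frozenset({"insulin"}), seed=seed)
        return S.simulate_dataset(cfg)

    def test_recovers_planted_log_scale_coefficients(self):
        df = self._multiplicative_cohort()
        spec = M.ModelSpec("partition", "insulin", stratum="adolescents",
                           covariates=(), estimator="pooled_ols",
                           variance="conventional")
        res = M.log_sensitivity(spec, df)
        assert res.beta("mvpa") == pytest.approx(-0.08, abs=1e-8)
        assert res.beta("sed") == pytest.approx(0.01, abs=1e-8)
        assert res.spec.log_outcome

    def test_sign_preserved_between_raw_and_log_fits(self):
        df = self._multiplicative_cohort(residual=0.3, seed=5)
        spec = M.ModelSpec("partition", "insulin", stratum="adolescents",
                           covariates=(), estimator="pooled_ols",
                           variance="conventional")
        raw = M.fit(spec, df)
        logged = M.log_sensitivity(spec, df)
        assert np.sign(raw.beta("mvpa")) == np.sign(logged.beta("mvpa")) == -1

    def test_nonpositive_outcome_errors_with_rows(self, noisy_cohort):
        df = noisy_cohort.copy()
        df.loc[df.index[0], "wc"] = 0.0
        spec = M.ModelSpec("partition", "wc", stratum=None)
        with pytest.raises(InputError, match="positive"):
            M.log_sensitivity(spec, df)


class TestSignificanceFlags:
    @pytest.mark.parametrize("p,flag", [(0.2, ""), (0.049, "*"), (0.01, "*"),
                                        (0.001, "**"), (1e-6, "**")])
    def test_footnote_convention(self, p, flag):
        assert M.significance_flag(p) == flag
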