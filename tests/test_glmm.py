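"""Mixed-model inference suite: fitting, tests, contrasts, study filters."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from tempopred import glmm
from tempopred.glmm import ModelSpec

from conftest import simulate_gamma_log_data, simulate_gaussian_data, simulate_logit_data


class TestFitGLMM:
    def test_single_subject_reduces_to_logistic(self):
        y = np.r_[np.ones(80), np.zeros(20)]
        df = pd.DataFrame({"subject": "A", "y": y})
        fit = glmm.fit_glmm(df, ModelSpec(response="y", family="binomial"))
        assert fit.coef["Intercept"] == pytest.approx(logit(0.8), abs=1e-6)
        assert fit.boundary  # random-intercept variance collapses to zero

    def test_binomial_parameter_recovery(self):
        rng = np.random.default_rng(42)
        beta0, beta1, tau = 0.5, -0.3, 0.5
        n_rep, within = 20, 0
        for _ in range(n_rep):
            df = simulate_logit_data(rng, beta0=beta0, beta1=beta1, tau=tau)
            fit = glmm.fit_glmm(df, ModelSpec(response="y", family="binomial", fixed=("x",)))
            ok = (
                abs(fit.coef["Intercept"] - beta0) < 3 * fit.se["Intercept"]
                and abs(fit.coef["x"] - beta1) < 3 * fit.se["x"]
            )
            within += ok
        # each replicate covers with ~99.7% probability
        assert within >= n_rep - 2

    def test_gamma_log_parameter_recovery(self):
        rng = np.random.default_rng(43)
        beta0, beta1 = 6.0, 0.1
        n_rep, within = 10, 0
        for _ in range(n_rep):
            df = simulate_gamma_log_data(rng, beta0=beta0, beta1=beta1)
            fit = glmm.fit_glmm(
                df, ModelSpec(response="y", family="gamma", link="log", fixed=("x",))
            )
            within += (
                abs(fit.coef["Intercept"] - beta0) < 3 * fit.se["Intercept"]
                and abs(fit.coef["x"] - beta1) < 3 * fit.se["x"]
            )
        assert within >= n_rep - 1

    def test_matches_lme4_laplace_fit(self, tmp_path):
        # independent oracle: glmer Laplace fit on the same data
        rng = np.random.default_rng(7)
        df = simulate_logit_data(rng, n_subjects=8, n_per_subject=60)
        fit = glmm.fit_glmm(df, ModelSpec(response="y", family="binomial", fixed=("x",)))
        csv = tmp_path / "dat.csv"
        df.to_csv(csv, index=False)
        rscript = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ x + (1|subject), data=d, family=binomial)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)), sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        )
        b0, b1, tau, ll = map(float, out.stdout.strip().splitlines())
        assert fit.coef["Intercept"] == pytest.approx(b0, abs=2e-3)
        assert fit.coef["x"] == pytest.approx(b1, abs=2e-3)
        assert fit.random_sd["intercept_sd"] == pytest.approx(tau, abs=5e-3)
        assert fit.loglik == pytest.approx(ll, abs=1e-2)


class TestLRT:
    def test_identical_models_give_zero(self):
        rng = np.random.default_rng(1)
        df = simulate_gaussian_data(rng)
        spec = ModelSpec(response="y", family="gaussian", fixed=("x",))
        f1 = glmm.fit_glmm(df, spec)
        f2 = glmm.fit_glmm(df, spec)
        res = glmm.lrt(f1, f2)
        assert res.chi2 == pytest.approx(0.0, abs=1e-6)
        assert res.p == 1.0

    def test_different_data_rejected(self):
        rng = np.random.default_rng(1)
        spec = ModelSpec(response="y", family="gaussian")
        f1 = glmm.fit_glmm(simulate_gaussian_data(rng), spec)
        f2 = glmm.fit_glmm(simulate_gaussian_data(rng, n_per_subject=20), spec)
        with pytest.raises(ValueError):
            glmm.lrt(f1, f2)

    def test_null_rejection_rate_at_nominal_level(self):
        # fixed-effect addition under a true null: size ~ 5%
        rng = np.random.default_rng(99)
        n_rep, rejects = 100, 0
        for _ in range(n_rep):
            df = simulate_gaussian_data(rng, beta1=0.0)
            null = glmm.fit_glmm(df, ModelSpec(response="y", family="gaussian"),
                                 compute_se=False)
            full = glmm.fit_glmm(
                df, ModelSpec(response="y", family="gaussian", fixed=("x",)),
                compute_se=False,
            )
            rejects += glmm.lrt(null, full).p < 0.05
        rate = rejects / n_rep
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestWald:
    def test_one_df_equals_z_squared(self, small_cohort_features):
        fit = glmm.fit_glmm(
            small_cohort_features,
            ModelSpec(response="correct", family="binomial", fixed=("global_std",)),
        )
        w = glmm.wald_type2(fit)
        z2 = (fit.coef["global_std"] / fit.se["global_std"]) ** 2
        assert w.loc[w.term == "global_std", "chi2"].iloc[0] == pytest.approx(
            z2, abs=1e-9
        )

    def test_wald_consistent_with_lrt(self):
        rng = np.random.default_rng(3)
        df = simulate_gaussian_data(rng, beta1=0.4, n_subjects=15, n_per_subject=40)
        full = glmm.fit_glmm(df, ModelSpec(response="y", family="gaussian", fixed=("x",)))
        null = glmm.fit_glmm(df, ModelSpec(response="y", family="gaussian"),
                             compute_se=False)
        chi2_w = glmm.wald_type2(full)["chi2"].iloc[0]
        chi2_l = glmm.lrt(null, full).chi2
        assert chi2_w == pytest.approx(chi2_l, rel=0.10)


class TestTukey:
    def test_two_level_adjustment_is_identity(self):
        rng = np.random.default_rng(5)
        df = simulate_gaussian_data(rng, n_subjects=8)
        df["lev"] = np.where(df["x"] > 0, "a", "b")
        fit = glmm.fit_glmm(df, ModelSpec(response="y", family="gaussian", factor="lev"))
        tab = glmm.pairwise_tukey(fit)
        assert len(tab) == 1
        assert tab["p_tukey"].iloc[0] == pytest.approx(
            tab["p_unadjusted"].iloc[0], abs=1e-6
        )

    def test_six_levels_give_15_contrasts(self, small_cohort_features):
        feats = small_cohort_features.assign(
            cond=small_cohort_features["condition_std_ms"].astype(str)
        )
        fit = glmm.fit_glmm(
            feats, ModelSpec(response="correct", family="binomial", factor="cond")
        )
        tab = glmm.pairwise_tukey(fit)
        assert len(tab) == 15
        assert (tab["p_tukey"] >= tab["p_unadjusted"] - 1e-12).all()
        pairs = {frozenset((a, b)) for a, b in zip(tab.level_a, tab.level_b)}
        assert len(pairs) == 15

    def test_null_familywise_error_controlled(self):
        # all level means equal: probability of any adjusted p < .05 stays near 5%
        rng = np.random.default_rng(11)
        n_rep, hits = 60, 0
        x = np.repeat(np.arange(6), 10)
        for _ in range(n_rep):
            df = simulate_gaussian_data(
                rng, n_subjects=8, n_per_subject=60, beta1=0.0, x=x
            )
            df["lev"] = np.tile([str(k) for k in x], 8)
            fit = glmm.fit_glmm(
                df, ModelSpec(response="y", family="gaussian", factor="lev")
            )
            hits += (glmm.pairwise_tukey(fit)["p_tukey"] < 0.05).any()
        rate = hits / n_rep
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestLocalGlobal:
    def test_or_reparameterization_identity(self, small_cohort_features):
        feats = small_cohort_features
        spec = ModelSpec(response="correct", family="binomial", fixed=("global_std",))
        fit = glmm.fit_glmm(feats, spec)
        feats2 = feats.assign(global_std=feats["global_std"] * 2.0)
        fit2 = glmm.fit_glmm(feats2, spec)
        assert fit2.coef["global_std"] == pytest.approx(
            fit.coef["global_std"] / 2.0, rel=1e-3
        )

    @pytest.mark.parametrize("planted", ["local", "global"])
    def test_planted_effect_lands_on_the_right_predictor(self, planted):
        from tempopred import history_stats, observer

        hits_planted, hits_null = 0, 0
        n_rep = 3
        rng = np.random.default_rng(55 if planted == "local" else 56)
        for _ in range(n_rep):
            if planted == "local":
                params = observer.ObserverParams(
                    acc_slope_global=0.0, acc_slope_local=0.0020, local_window=4
                )
            else:
                params = observer.ObserverParams(acc_slope_global=0.0015,
                                                 acc_slope_local=0.0)
            trials, _ = observer.simulate_cohort(10, params, rng)
            feats = history_stats.cohort_features(trials).dropna(subset=["correct"])
            feats = feats[feats["condition_std_ms"] > 0]
            row = glmm.fit_local_global(feats, n_std=4 if planted == "local" else 2)
            key = "local_std_25" if planted == "local" else "global_std_25"
            other = "global_std_25" if planted == "local" else "local_std_25"
            hits_planted += row[key]["ci_high"] < 1.0  # planted harm detected
            hits_null += row[other]["ci_low"] <= 1.0  # null predictor not inflated
        assert hits_planted == n_rep
        assert hits_null >= n_rep - 1


class TestRestrictAndRatings:
    def test_restriction_filter_arithmetic(self):
        tab = pd.DataFrame({"last_soa_ms": [475.0, 500.0, 525.0, 500.0]})
        assert len(glmm.restrict_to_mean_soa(tab)) == 2
        periodic = pd.DataFrame({"last_soa_ms": [500.0] * 7})
        assert len(glmm.restrict_to_mean_soa(periodic)) == 7
        with pytest.warns(UserWarning):
            glmm.restrict_to_mean_soa(pd.DataFrame({"last_soa_ms": [475.0]}))

    def test_kept_fraction_matches_grid_mass(self):
        from tempopred.sequences import ConditionSpec, build_block, build_soa_distribution
        from tempopred import history_stats

        rng = np.random.default_rng(6)
        spec = ConditionSpec(50.0)
        mass = build_soa_distribution(spec).mass_at(500.0)
        rows = []
        for _ in range(30):
            feats = history_stats.compute_history_features(build_block(spec, rng))
            rows.append(feats)
        feats = pd.concat(rows)
        frac = (feats["last_soa_ms"] == 500.0).mean()
        se = np.sqrt(mass * (1 - mass) / len(feats))
        assert abs(frac - mass) < 3 * se

    def test_rating_models_null_and_power(self, small_cohort, small_cohort_features):
        _, ratings = small_cohort
        out = glmm.rating_models(small_cohort_features, ratings)
        # ratings decline steeply with STD by construction: strong STD effect
        fit = out["rating_on_std_fit"]
        z = fit.coef["global_std"] / fit.se["global_std"]
        assert fit.coef["global_std"] < 0
        assert abs(z) > 4
        # given STD, ratings carry no extra information about accuracy
        assert out["lrt_add_rating"].chi2 >= 0.0

    def test_constant_ratings_warn(self, small_cohort_features):
        ratings = pd.DataFrame(
            {
                "subject": ["S01"] * 12 + ["S02"] * 12,
                "block": list(range(1, 13)) * 2,
                "condition_std_ms": list(np.repeat([0, 25, 50, 75, 100, 150], 2)) * 2,
                "rating": 5.0,
            }
        )
        with pytest.warns(UserWarning, match="constant"):
            glmm.rating_models(small_cohort_features, ratings)


class TestOutlierRaters:
    def _ratings(self, slopes, noise=0.0):
        rows = []
        stds = np.repeat([0.0, 25.0, 50.0, 75.0, 100.0, 150.0], 2)
        for s_i, slope in enumerate(slopes):
            for b_i, std in enumerate(stds, start=1):
                rows.append((f"S{s_i:02d}", b_i, std, 8.0 + slope * std))
        return pd.DataFrame(rows, columns=["subject", "block", "condition_std_ms", "rating"])

    def test_identical_slopes_keep_everyone(self):
        out = glmm.exclude_outlier_raters(self._ratings([-0.02] * 8))
        assert out["excluded"] == []

    def test_sign_flipped_extreme_subject_excluded(self):
        rng = np.random.default_rng(2)
        slopes = list(-0.02 + 0.002 * rng.normal(size=18)) + [+0.03]
        out = glmm.exclude_outlier_raters(self._ratings(slopes))
        assert "S18" in out["excluded"]

    def test_fences_match_bruteforce_quartiles(self):
        slopes = [-0.040, -0.030, -0.025, -0.020, -0.018, -0.015, -0.010, 0.020]
        out = glmm.exclude_outlier_raters(self._ratings(slopes))
        q1, q3 = np.quantile(slopes, [0.25, 0.75])
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        assert out["fences"] == pytest.approx((lo, hi))
        expected_excluded = [
            f"S{i:02d}" for i, s in enumerate(slopes) if not lo <= s <= hi
        ]
        assert out["excluded"] == expected_excluded

    def test_too_few_subjects_raise(self):
        with pytest.raises(ValueError):
            glmm.exclude_outlier_raters(self._ratings([-0.02, -0.01, 0.0]))
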