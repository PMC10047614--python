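import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from fidescape.fid_adjust import adjust_table
from fidescape.glmm import (ScalingError, build_design, check_collinearity,
                            classify_effects, cooks_distances, fit_glmm,
                            influence_refit, model1_spec, model2_spec,
                            overdispersion_check, scale_predictors)
from fidescape.simulate import SimulationParams, simulate_encounters_tabular

CLEAN = dict(p_non_response=0.0, p_walk_run=0.0, p_refuge_unknown=0.0)


def sim_adjusted(**kw):
    params = SimulationParams(**{**CLEAN, **kw})
    table = simulate_encounters_tabular(params)
    table, _ = adjust_table(table)
    return table


class TestScaling:
    def test_hand_z_scores(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, scalers = scale_predictors(t, ["x"])
        assert np.allclose(out["x"], [-1.0, 0.0, 1.0])   # sample SD = 1
        assert scalers["x"] == (2.0, 1.0)

    def test_random_column_moments(self, rng):
        t = pd.DataFrame({"x": rng.normal(3, 7, 500)})
        out, _ = scale_predictors(t, ["x"])
        assert abs(out["x"].mean()) < 1e-12
        assert abs(out["x"].std(ddof=1) - 1) < 1e-12

    def test_constant_column_is_an_error_naming_the_term(self):
        t = pd.DataFrame({"flat": np.ones(10)})
        with pytest.raises(ScalingError, match="flat"):
            scale_predictors(t, ["flat"])


class TestCollinearity:
    def test_duplicate_column_is_flagged(self, rng):
        x = rng.normal(size=100)
        t = pd.DataFrame({"a": x, "b": x})
        rep = check_collinearity(t, ["a", "b"])
        assert rep.max_abs_pairwise_correlation == pytest.approx(1.0)
        assert rep.collinear_pairs

    def test_independent_columns_pass(self, rng):
        t = pd.DataFrame({"a": rng.normal(size=1000), "b": rng.normal(size=1000)})
        assert not check_collinearity(t, ["a", "b"]).collinear_pairs

    def test_engineered_correlation_0p6_is_flagged(self, rng):
        x = rng.normal(size=1000)
        e = rng.normal(size=1000)
        e -= e @ x / (x @ x) * x          # orthogonalise exactly
        y = 0.6 * x / x.std() + np.sqrt(1 - 0.36) * e / e.std()
        t = pd.DataFrame({"a": x, "b": y})
        rep = check_collinearity(t, ["a", "b"])
        assert rep.collinear_pairs
        assert rep.max_abs_pairwise_correlation == pytest.approx(0.6, abs=0.02)


class TestFitOracles:
    def test_gaussian_without_random_effect_equals_ols(self):
        t = sim_adjusted(seed=11, family="gaussian")
        spec = model1_spec("gaussian")
        fit = fit_glmm(spec, t, include_random=False)
        y, X, names, *_ = build_design(spec, t)
        ols = sm.OLS(y, X).fit()
        assert np.allclose(fit.table["estimate"], ols.params, atol=1e-6)
        assert np.allclose(fit.table["se"], ols.bse, atol=1e-6)

    def test_poisson_single_park_equals_glm(self):
        t = sim_adjusted(seed=12, family="poisson", n_parks=2,
                         encounters_per_park=100)
        t["park_id"] = "P0"                      # collapse to one level
        spec = model2_spec("poisson")
        fit = fit_glmm(spec, t)
        y, X, *_ = build_design(spec, t)
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert fit.n_groups == 1
        assert np.allclose(fit.table["estimate"], glm.params, atol=1e-6)
        assert np.allclose(fit.table["se"], glm.bse, atol=1e-6)

    def test_scaled_coefficients_back_transform_to_unscaled_fit(self):
        """z-scaling is a reparameterisation: dividing each scaled gaussian
        coefficient by its predictor's SD recovers the unscaled-fit slope."""
        from dataclasses import replace
        t = sim_adjusted(seed=16, family="gaussian")
        spec = model1_spec("gaussian")
        fit_scaled = fit_glmm(spec, t, include_random=False)
        _, _, _, _, _, scalers = build_design(spec, t)
        fit_raw = fit_glmm(replace(spec, scale_predictors=False), t,
                           include_random=False)
        for term, col in (("RC", "rc_prop"), ("PD", "pd_per_m"),
                          ("StD", "std_m")):
            sd = scalers[col][1]
            assert fit_scaled.table.loc[term, "estimate"] / sd == pytest.approx(
                fit_raw.table.loc[term, "estimate"], abs=1e-6)

    def test_poisson_recovery_covers_generating_value(self):
        """Wald 95% CIs are calibrated: over replicates, nearly all cover the
        generating coefficient (any single CI may miss by chance)."""
        covered, estimates = 0, []
        for seed in range(130, 140):
            t = sim_adjusted(seed=seed, family="poisson", beta_rc=-0.5)
            fit = fit_glmm(model2_spec("poisson"), t)
            row = fit.table.loc["RC"]
            covered += row["ci_low"] <= -0.5 <= row["ci_high"]
            estimates.append(row["estimate"])
            assert fit.statistic_kind == "z"
        assert covered >= 8
        assert np.mean(estimates) == pytest.approx(-0.5, abs=0.1)

    def test_nb_random_variance_recovery_at_large_n(self):
        t = sim_adjusted(seed=14, family="negative_binomial", park_sd=0.8,
                         n_parks=40, encounters_per_park=25)
        fit = fit_glmm(model2_spec("negative_binomial"), t)
        assert 0.5 * 0.8 ** 2 <= fit.random_sd ** 2 <= 1.5 * 0.8 ** 2
        assert fit.nb_alpha == pytest.approx(0.5, rel=0.5)

    def test_boundary_random_variance_reports_fixed_only_refit(self):
        t = sim_adjusted(seed=15, family="poisson", park_sd=0.0,
                         n_parks=5, encounters_per_park=60)
        fit = fit_glmm(model2_spec("poisson"), t)
        if fit.boundary:     # sigma estimated at ~0, as expected without park effects
            assert fit.fixed_only is not None
            assert np.allclose(fit.fixed_only.table["estimate"],
                               fit.table["estimate"], atol=0.05)
        else:
            assert fit.random_sd < 0.15


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="R oracle not on PATH")
class TestAgainstRGlmer:
    """Independent cross-check: lme4's Laplace glmer on identical data."""

    def test_poisson_glmm_matches_lme4(self, tmp_path):
        t = sim_adjusted(seed=21, family="poisson", n_parks=15,
                         encounters_per_park=12)
        spec = model2_spec("poisson")
        fit = fit_glmm(spec, t)
        y, X, names, gidx, *_ = build_design(spec, t)
        d = pd.DataFrame(X[:, 1:], columns=["fa", "rc", "pdv", "farc", "fapd"])
        d["y"] = y
        d["g"] = gidx
        csv = tmp_path / "d.csv"
        d.to_csv(csv, index=False)
        rfile = tmp_path / "fit.R"
        rfile.write_text(
            f'd <- read.csv("{csv}")\n'
            'suppressMessages(library(lme4))\n'
            'm <- glmer(y ~ fa + rc + pdv + farc + fapd + (1|g), data=d,'
            ' family=poisson)\n'
            'co <- summary(m)$coefficients\n'
            'write.csv(co, stdout())\n'
            'cat("RANDSD", sqrt(unlist(VarCorr(m))), "\\n")\n')
        out = subprocess.run(["Rscript", str(rfile)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        lines = [l for l in out.stdout.splitlines() if l and not l.startswith("RANDSD")]
        from io import StringIO
        rtab = pd.read_csv(StringIO("\n".join(lines)), index_col=0)
        rand_sd = float(next(l for l in out.stdout.splitlines()
                             if l.startswith("RANDSD")).split()[1])
        assert np.allclose(fit.table["estimate"], rtab["Estimate"], atol=5e-3)
        assert np.allclose(fit.table["se"], rtab["Std. Error"], atol=5e-3)
        assert fit.random_sd == pytest.approx(rand_sd, abs=2e-2)


class TestOverdispersion:
    def test_true_poisson_ratio_near_one(self):
        t = sim_adjusted(seed=31, family="poisson", n_parks=20,
                         encounters_per_park=50)
        fit = fit_glmm(model2_spec("poisson"), t)
        rep = overdispersion_check(fit)
        assert 0.8 <= rep.dispersion_ratio <= 1.2
        assert not rep.nb_recommended

    def test_nb_data_fit_as_poisson_is_flagged(self):
        t = sim_adjusted(seed=32, family="negative_binomial", nb_dispersion=0.5,
                         n_parks=20, encounters_per_park=50)
        fit = fit_glmm(model2_spec("poisson"), t)
        rep = overdispersion_check(fit)
        assert rep.dispersion_ratio > 1.5
        assert rep.nb_recommended

    def test_empty_residuals_error(self):
        from fidescape.glmm import FitResult
        empty = FitResult(table=pd.DataFrame(), family="poisson",
                          statistic_kind="z", random_sd=0, converged=True,
                          _y=np.array([]), _mu=np.array([]),
                          _X=np.empty((0, 2)))
        with pytest.raises(ValueError):
            overdispersion_check(empty)


class TestInfluence:
    def test_no_influential_rows_leaves_fit_unchanged(self):
        t = sim_adjusted(seed=41, family="gaussian")
        spec = model2_spec("gaussian_log")
        fit = fit_glmm(spec, t)
        rep = influence_refit(spec, t, fit, threshold=np.inf)
        assert rep.cooks_influential_rows == []
        assert rep.refit is fit
        assert not rep.refit_qualitative_change

    def test_planted_outlier_is_flagged_and_removal_restores_recovery(self):
        t = sim_adjusted(seed=42, family="gaussian", beta_rc=-0.5)
        spec = model2_spec("gaussian_log")
        idx = t.index[7]
        t.loc[idx, "distance_fled_m"] = 1e5    # gross outlier
        fit = fit_glmm(spec, t)
        rep = influence_refit(spec, t, fit)
        assert idx in rep.cooks_influential_rows
        row = rep.refit.table.loc["RC"]
        assert row["ci_low"] <= -0.5 <= row["ci_high"]

    def test_refuses_refit_on_too_few_rows(self):
        t = sim_adjusted(seed=43, family="gaussian", n_parks=2,
                         encounters_per_park=6)
        spec = model2_spec("gaussian_log")
        fit = fit_glmm(spec, t)
        d = cooks_distances(fit)
        with pytest.raises(ValueError, match="refused"):
            influence_refit(spec, t, fit, threshold=float(np.sort(d)[2]))


class TestEffectClassification:
    @pytest.mark.parametrize("p, label", [
        (0.034, "significant"),   # a clear effect
        (0.049, "significant"),
        (0.050, "trend"),         # the trend band is [0.05, 0.10)
        (0.054, "trend"),
        (0.099, "trend"),
        (0.100, "none"),          # boundary: < 0.10 strictly
        (0.5, "none"),
    ])
    def test_bands(self, p, label):
        tab = pd.DataFrame({"estimate": [1.0, 0.2], "se": [0.1, 0.1],
                            "statistic": [10.0, 1.0], "p": [0.001, p],
                            "ci_low": [0.8, 0.0], "ci_high": [1.2, 0.4]},
                           index=["Intercept", "RC"])
        from fidescape.glmm import FitResult
        fit = FitResult(table=tab, family="poisson", statistic_kind="z",
                        random_sd=0.1, converged=True)
        assert classify_effects(fit)["RC"] == label
        assert "Intercept" not in classify_effects(fit)
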