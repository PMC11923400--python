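import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from firetraits.models import (
    FireResponseModel,
    LeafTraitModel,
    fit_leaf_trait_lm,
    fit_logistic_quadratic,
    tjur_r2,
)


def _expit(v):
    return 1.0 / (1.0 + np.exp(-v))


def _simulate_table(beta, n, rng, x_low=-0.7, x_high=1.7, growth_form=None):
    x = rng.uniform(x_low, x_high, n)
    p = _expit(beta[0] + beta[1] * x + beta[2] * x**2)
    table = pd.DataFrame({
        "resprouter": rng.random(n) < p,
        "fires_per_century": 10.0**x,
    })
    if growth_form is not None:
        table["growth_form"] = growth_form
    return table


class TestLogisticQuadratic:
    def test_brute_force_likelihood_oracle(self):
        # tiny fixed dataset: IRLS must match direct likelihood maximisation
        table = pd.DataFrame({
            "resprouter": [True, True, False, True, False, False, True, False],
            "fires_per_century": [0.5, 1.0, 2.0, 4.0, 8.0, 0.25, 1.5, 3.0],
        })
        fit = fit_logistic_quadratic(table, group_col=None)
        x = np.log10(table["fires_per_century"].to_numpy())
        y = table["resprouter"].to_numpy()

        def neg_ll(b):
            eta = b[0] + b[1] * x + b[2] * x**2
            return -(np.where(y, eta, 0) - np.log1p(np.exp(eta))).sum()

        best = np.inf
        for start in ([0, 0, 0], [1, 1, -1], [-1, 0.5, 0.5], [0.5, -1, 0]):
            res = optimize.minimize(neg_ll, start, method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-14,
                                             "maxiter": 5000})
            best = min(best, res.fun)
        assert fit.llf == pytest.approx(-best, abs=1e-6)

    def test_null_simulation_recovers_zero_effects(self):
        rng = np.random.default_rng(21)
        n = 5000
        x = rng.uniform(-1, 1.5, n)
        table = pd.DataFrame({
            "resprouter": rng.random(n) < 0.3,
            "fires_per_century": 10.0**x,
        })
        fit = fit_logistic_quadratic(table, group_col=None)
        for term in ("log10_fires", "log10_fires_sq"):
            assert abs(fit.params[term]) < 3 * fit.bse[term]
        logit_p = np.log(0.3 / 0.7)
        assert abs(fit.params["intercept"] - logit_p) < 3 * fit.bse["intercept"]

    def test_recovery_of_published_scale_coefficients(self):
        rng = np.random.default_rng(8)
        beta = (0.88, 0.70, -1.17)
        table = _simulate_table(beta, 5000, rng)
        fit = fit_logistic_quadratic(table, group_col=None)
        for term, truth in zip(("intercept", "log10_fires", "log10_fires_sq"),
                               beta):
            assert abs(fit.params[term] - truth) < 3 * fit.bse[term]

    def test_interaction_model_treatment_coding(self):
        rng = np.random.default_rng(9)
        n = 4000
        herb = _simulate_table((0.9, 0.7, -1.2), n, rng, growth_form="herbaceous")
        woody = _simulate_table((0.5, 0.4, 0.0), n, rng, growth_form="woody")
        fit = fit_logistic_quadratic(pd.concat([herb, woody]))
        # herbaceous is the reference: base terms recover the herb curve
        assert abs(fit.params["intercept"] - 0.9) < 3 * fit.bse["intercept"]
        assert abs(fit.params["woody"] - (0.5 - 0.9)) < 3 * fit.bse["woody"]
        assert abs(fit.params["log10_fires_sq:woody"] - 1.2) \
            < 3 * fit.bse["log10_fires_sq:woody"]

    def test_single_class_response_rejected(self):
        table = pd.DataFrame({"resprouter": [True] * 5,
                              "fires_per_century": [1, 2, 3, 4, 5.0]})
        with pytest.raises(ValueError, match="single class"):
            fit_logistic_quadratic(table, group_col=None)

    def test_separation_is_flagged(self):
        table = pd.DataFrame({
            "resprouter": [False] * 10 + [True] * 10,
            "fires_per_century": np.r_[np.linspace(0.1, 0.9, 10),
                                       np.linspace(2, 30, 10)],
        })
        fit = fit_logistic_quadratic(table, group_col=None)
        assert fit.separation_flag and not fit.converged

    def test_wald_ci_coverage_calibration(self):
        # ~95 % of 95 % CIs should cover each true coefficient
        rng = np.random.default_rng(31)
        beta = (0.88, 0.70, -1.17)
        n_rep, n = 200, 1000
        x = rng.uniform(-0.7, 1.7, n)
        F = 10.0**x
        p = _expit(beta[0] + beta[1] * x + beta[2] * x**2)
        cover = np.zeros(3)
        for _ in range(n_rep):
            table = pd.DataFrame({"resprouter": rng.random(n) < p,
                                  "fires_per_century": F})
            fit = fit_logistic_quadratic(table, group_col=None)
            ci = fit.conf_int()
            for j, term in enumerate(("intercept", "log10_fires",
                                      "log10_fires_sq")):
                cover[j] += (ci.loc[term, "low"] <= beta[j] <= ci.loc[term, "high"])
        cover /= n_rep
        assert ((cover >= 0.92) & (cover <= 0.98)).all()


class TestOddsRatios:
    def test_duality_with_coefficients(self):
        rng = np.random.default_rng(5)
        table = _simulate_table((0.8, 0.6, -1.0), 2000, rng)
        fit = fit_logistic_quadratic(table, group_col=None)
        orr = fit.odds_ratios()
        np.testing.assert_allclose(orr["odds_ratio"],
                                   np.exp(fit.params), rtol=1e-12)
        np.testing.assert_allclose(orr["or_low"],
                                   np.exp(fit.conf_int()["low"]), rtol=1e-12)
        assert (orr["or_low"] <= orr["or_high"]).all()

    @pytest.mark.parametrize("beta, expected", [(0.70, 2.01), (-1.17, 0.31),
                                                (-0.38, 0.68), (0.0, 1.0)])
    def test_published_rounding(self, beta, expected):
        assert round(float(np.exp(beta)), 2) == expected


class TestTjurR2:
    def test_perfect_discrimination(self):
        assert tjur_r2([1, 1, 0, 0], [True, True, False, False]) == 1.0

    def test_constant_probability_is_zero(self):
        assert tjur_r2([0.4] * 6, [True, False] * 3) == 0.0

    def test_hand_arithmetic(self):
        assert tjur_r2([0.8, 0.6, 0.3, 0.3],
                       [True, True, False, False]) == pytest.approx(0.40)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tjur_r2([0.5, 0.6], [True, True])


class TestPredictCurve:
    def _fixed_fit(self):
        rng = np.random.default_rng(3)
        return fit_logistic_quadratic(
            _simulate_table((0.88, 0.70, -1.17), 3000, rng), group_col=None)

    def test_probability_at_unit_frequency_matches_intercept(self):
        fit = self._fixed_fit()
        pred = fit.predict_curve([1.0])
        b0 = fit.params["intercept"]
        assert pred["probability"].iloc[0] == pytest.approx(_expit(b0), abs=1e-12)

    def test_band_contains_point_estimate_and_stays_in_unit_interval(self):
        fit = self._fixed_fit()
        pred = fit.predict_curve(np.geomspace(0.1, 50, 40))
        assert ((pred["ci_low"] <= pred["probability"])
                & (pred["probability"] <= pred["ci_high"])).all()
        assert (pred["ci_low"] >= 0).all() and (pred["ci_high"] <= 1).all()

    def test_flat_curve_when_slope_terms_vanish(self):
        rng = np.random.default_rng(14)
        n = 3000
        table = pd.DataFrame({
            "resprouter": rng.random(n) < 0.4,
            "fires_per_century": 10.0**rng.uniform(-1, 1.5, n),
        })
        fit = fit_logistic_quadratic(table, group_col=None)
        pred = fit.predict_curve([0.1, 1.0, 10.0])
        assert pred["probability"].max() - pred["probability"].min() < 0.05


class TestQuadraticPeak:
    def test_published_scale_peak_location(self):
        # beta1 = 0.70, beta2 = -1.17 -> x* = 0.2991, F* = 1.992
        class Dummy:  # exercise the formula through a real fit instead
            pass
        rng = np.random.default_rng(10)
        table = _simulate_table((0.88, 0.70, -1.17), 200_000, rng)
        fit = fit_logistic_quadratic(table, group_col=None)
        peak = fit.peak()
        assert peak["has_peak"]
        assert peak["peak_fires_per_century"] == pytest.approx(1.992, rel=0.08)

    def test_convex_curve_reports_no_peak(self):
        rng = np.random.default_rng(11)
        table = _simulate_table((0.0, 0.0, 0.8), 5000, rng)
        fit = fit_logistic_quadratic(table, group_col=None)
        assert fit.peak()["has_peak"] is False

    def test_symmetric_curve_peaks_at_unit_frequency(self):
        rng = np.random.default_rng(12)
        table = _simulate_table((0.5, 0.0, -1.0), 100_000, rng,
                                x_low=-1.2, x_high=1.2)
        fit = fit_logistic_quadratic(table, group_col=None)
        assert fit.peak()["peak_fires_per_century"] == pytest.approx(1.0, abs=0.1)

    def test_rescaling_F_shifts_peak_by_same_factor(self):
        rng = np.random.default_rng(13)
        table = _simulate_table((0.88, 0.70, -1.17), 20_000, rng)
        fit1 = fit_logistic_quadratic(table, group_col=None)
        scaled = table.assign(fires_per_century=table["fires_per_century"] * 3.0)
        fit2 = fit_logistic_quadratic(scaled, group_col=None)
        assert fit2.peak()["peak_fires_per_century"] == pytest.approx(
            3.0 * fit1.peak()["peak_fires_per_century"], rel=1e-6)


class TestLeafTraitLm:
    def _profiles(self, rng, effect=0.0, n=1000):
        # 2x2 design, herb non-strategist baseline 2.0, sd 0.25
        rows = []
        for gf in ("herbaceous", "woody"):
            for strat in (False, True):
                mu = 2.0 + 0.4 * (gf == "woody") + effect * strat
                vals = rng.normal(mu, 0.25, n)
                for v in vals:
                    rows.append({"growth_form": gf, "resprouter": strat,
                                 "mean_lma": 10.0**v})
        return pd.DataFrame(rows)

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(17)
        profiles = self._profiles(rng, effect=0.2, n=10)
        fit = fit_leaf_trait_lm(profiles)
        X = fit.model.exog.to_numpy()
        y = fit.model.endog
        beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.params.to_numpy(), beta_ne, atol=1e-8)

    def test_null_effects_within_3se(self):
        rng = np.random.default_rng(18)
        fit = fit_leaf_trait_lm(self._profiles(rng, effect=0.0, n=1000))
        assert abs(fit.params["resprouter"]) < 3 * fit.bse["resprouter"]
        assert abs(fit.params["resprouter:woody"]) < 3 * fit.bse["resprouter:woody"]

    def test_strategy_effect_recovery(self):
        rng = np.random.default_rng(19)
        fit = fit_leaf_trait_lm(self._profiles(rng, effect=0.2, n=1000))
        assert abs(fit.params["resprouter"] - 0.2) < 3 * fit.bse["resprouter"]

    def test_collinear_design_rejected(self):
        profiles = pd.DataFrame({
            "growth_form": ["woody"] * 4 + ["herbaceous"] * 4,
            "resprouter": [True] * 4 + [False] * 4,  # aliased with woody
            "mean_lma": [100, 110, 120, 130, 50, 60, 70, 80.0],
        })
        with pytest.raises(ValueError, match="aliased"):
            fit_leaf_trait_lm(profiles)


class TestEmmContrasts:
    def _fit(self, rng, effect=0.0, n=200):
        return TestLeafTraitLm()._profiles(rng, effect=effect, n=n)

    def test_identical_groups_give_null_contrast(self):
        rng = np.random.default_rng(23)
        fit = fit_leaf_trait_lm(self._fit(rng, effect=0.0, n=2000))
        for con in fit.emm_pairwise(adjust="tukey"):
            assert abs(con.estimate) < 0.03
            assert con.p_adjusted > 0.01

    def test_degenerate_family_equals_unadjusted(self):
        rng = np.random.default_rng(24)
        fit = fit_leaf_trait_lm(self._fit(rng, effect=0.1, n=50))
        p = {adj: [c.p_adjusted for c in fit.emm_pairwise(adjust=adj)]
             for adj in ("tukey", "bonferroni", "none")}
        # within-group family has one contrast over two means: no adjustment bites
        np.testing.assert_allclose(p["tukey"], p["none"], rtol=1e-12)
        np.testing.assert_allclose(p["bonferroni"], p["none"], rtol=1e-12)

    def test_family_of_four_means_adjusts_upward(self):
        rng = np.random.default_rng(25)
        fit = fit_leaf_trait_lm(self._fit(rng, effect=0.05, n=100))
        p_none = [c.p_adjusted for c in fit.emm_pairwise(adjust="none")]
        p_tuk = [c.p_adjusted for c in fit.emm_pairwise(adjust="tukey",
                                                        family="all")]
        p_bon = [c.p_adjusted for c in fit.emm_pairwise(adjust="bonferroni",
                                                        family="all")]
        assert all(t >= n for t, n in zip(p_tuk, p_none))
        assert all(b >= n for b, n in zip(p_bon, p_none))

    def test_power_and_sign_at_moderate_effect(self):
        rng = np.random.default_rng(26)
        fit = fit_leaf_trait_lm(self._fit(rng, effect=0.15, n=1000))
        for con in fit.emm_pairwise(adjust="tukey"):
            assert con.estimate > 0
            assert con.p_adjusted < 0.001

    def test_tukey_matches_studentized_range_reference(self):
        # independent check: Tukey p for the 4-mean family equals the
        # studentized-range tail computed directly from the contrast t
        rng = np.random.default_rng(27)
        fit = fit_leaf_trait_lm(self._fit(rng, effect=0.08, n=100))
        con = fit.emm_pairwise(adjust="tukey", family="all")[0]
        expected = stats.studentized_range.sf(abs(con.t) * np.sqrt(2), 4, con.df)
        assert con.p_adjusted == pytest.approx(float(expected), rel=1e-10)

    def test_unknown_adjustment_rejected(self):
        rng = np.random.default_rng(28)
        fit = fit_leaf_trait_lm(self._fit(rng, n=20))
        with pytest.raises(ValueError, match="unknown adjustment"):
            fit.emm_pairwise(adjust="scheffe")
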