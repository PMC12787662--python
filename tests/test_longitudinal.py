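"""Mixed-model fitting: REML, effective df, criteria, prediction, KS test."""

import numpy as np
import pandas as pd
import pytest

from tricadence import (
    DesignSpec,
    SeasonGenConfig,
    compare_models,
    fit_model,
    gen_season_dataset,
    ks_normality,
    model_criteria,
    predict_curve,
    weekly_percent_change,
)
from tricadence.longitudinal import (
    IllPosedCriteriaError,
    IncomparableFitsError,
    PredictionCurve,
    RankDeficiencyError,
)


def _frame(weeks, cadence, pids=None):
    n = len(weeks)
    pids = pids if pids is not None else [f"P{i % 2 + 1:02d}" for i in range(n)]
    return pd.DataFrame({
        "participant_id": pids, "week": weeks, "season": [1] * n, "cadence": cadence,
    })


class TestKsNormality:
    def test_gaussian_sample_not_rejected(self):
        rng = np.random.default_rng(11)
        stat, p = ks_normality(rng.standard_normal(1000), seed=0)
        assert p > 0.05

    def test_uniform_sample_rejected(self):
        rng = np.random.default_rng(12)
        stat, p = ks_normality(rng.uniform(0.0, 10.0, 500), seed=0)
        assert p < 0.01

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.full(20, 3.0))

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.array([1.0, 2.0, 3.0]))


class TestDegenerateOls:
    def test_no_random_effects_equals_closed_form_ols(self, ols_points):
        weeks, cadence = ols_points
        data = _frame(weeks, cadence)
        fit = fit_model(data, DesignSpec("linear", random_effects=()))
        X = np.column_stack([np.ones_like(weeks), weeks])
        beta_ols, *_ = np.linalg.lstsq(X, cadence, rcond=None)
        assert fit.beta0 == pytest.approx(beta_ols[0], abs=1e-8)
        assert fit.beta1 == pytest.approx(beta_ols[1], abs=1e-8)
        assert fit.edf_total == pytest.approx(2.0, abs=1e-8)

    def test_aic_matches_closed_form_gaussian_aic(self, ols_points):
        weeks, cadence = ols_points
        fit = fit_model(_frame(weeks, cadence), DesignSpec("linear", random_effects=()))
        n = len(weeks)
        X = np.column_stack([np.ones_like(weeks), weeks])
        beta, *_ = np.linalg.lstsq(X, cadence, rcond=None)
        rss = float(np.sum((cadence - X @ beta) ** 2))
        ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
        assert fit.aic == pytest.approx(-2 * ll + 2 * 2, abs=1e-6)

    def test_extra_predictor_never_decreases_loglik(self, ols_points):
        weeks, cadence = ols_points
        base = fit_model(_frame(weeks, cadence), DesignSpec("linear", random_effects=()))
        df2 = _frame(weeks, cadence)
        df2["season"] = [1, 2, 1, 2, 1, 2]  # irrelevant but admissible predictor
        bigger = fit_model(df2, DesignSpec("linear", random_effects=()))
        assert bigger.loglik >= base.loglik - 1e-9


class TestFitModel:
    def test_flat_truth_parameter_recovery(self):
        cfg = SeasonGenConfig(n_participants=8, weeks=tuple(range(10)), trend_shape="flat",
                              beta0=60.0, sd_eps=1.0, seed=13)
        data, _ = gen_season_dataset(cfg)
        fit = fit_model(data, DesignSpec("linear"))
        assert abs(fit.beta1) <= 2 * fit.se_beta["beta1"]
        assert abs(fit.beta0 - 60.0) <= 2 * fit.se_beta["beta0"]

    def test_smooth_stays_linear_on_linear_truth(self):
        """On linear-truth data the penalized smooth should carry little
        wiggle: its effective df stays near the one linear degree."""
        edfs = []
        for s in range(20):
            cfg = SeasonGenConfig(n_participants=10, weeks=tuple(range(12)),
                                  trend_shape="linear", beta0=62.0, beta1=0.2,
                                  sd_b0=3.0, sd_b1=0.1, sd_eps=2.0, seed=8000 + s)
            data, _ = gen_season_dataset(cfg)
            edfs.append(fit_model(data, DesignSpec("nonlinear")).edf_smooth)
        assert np.median(edfs) <= 1.5
        assert np.quantile(edfs, 0.9) <= 3.0

    def test_single_participant_rejected(self):
        data = _frame(np.arange(6.0), np.arange(6.0) + 60.0, pids=["P01"] * 6)
        with pytest.raises(RankDeficiencyError):
            fit_model(data, DesignSpec("linear"))

    def test_edf_smooth_monotone_in_lambda(self, ushape_season):
        data, _ = ushape_season
        edfs = []
        for loglam in (-6.0, -2.0, 0.0, 2.0, 6.0, 12.0):
            fit = fit_model(data, DesignSpec("nonlinear"),
                            log_lambda_override=np.array([0.0, loglam, 2.0, 2.0]))
            edfs.append(fit.edf_smooth)
        assert all(b <= a + 1e-8 for a, b in zip(edfs, edfs[1:]))

    def test_leverage_sum_equals_total_edf(self, linear_season):
        data, _ = linear_season
        fit = fit_model(data, DesignSpec("nonlinear"))
        B = fit._state.B
        Hinv = fit._cov / fit.var_eps
        leverages = np.einsum("ij,jk,ik->i", B, Hinv, B)
        assert np.sum(leverages) == pytest.approx(fit.edf_total, abs=1e-6)

    def test_random_slopes_are_pooled_toward_zero(self):
        cfg = SeasonGenConfig(n_participants=10, weeks=tuple(range(12)), trend_shape="flat",
                              beta0=62.0, sd_b0=3.0, sd_b1=0.15, sd_eps=2.0, seed=21)
        data, _ = gen_season_dataset(cfg)
        fit = fit_model(data, DesignSpec("linear"))
        resid_slopes = {}
        for pid, g in data.groupby("participant_id"):
            resid = g["cadence"] - (fit.beta0 + fit.beta1 * g["week"])
            resid_slopes[pid] = np.polyfit(g["week"], resid, 1)[0]
        for pid, b1 in fit.b1.items():
            assert abs(b1) <= abs(resid_slopes[pid]) + 0.05
        assert np.std(list(fit.b1.values())) <= np.std(list(resid_slopes.values()))


class TestComparison:
    def test_fit_against_itself_is_null(self, linear_season):
        data, _ = linear_season
        fit = fit_model(data, DesignSpec("linear"))
        cmp_ = compare_models(fit, fit)
        assert cmp_.D == 0.0 and cmp_.p == 1.0

    def test_different_datasets_rejected(self, linear_season, ushape_season):
        fit_a = fit_model(linear_season[0], DesignSpec("linear"))
        fit_b = fit_model(ushape_season[0], DesignSpec("nonlinear"))
        with pytest.raises(IncomparableFitsError):
            compare_models(fit_a, fit_b)

    def test_curved_truth_detected(self, ushape_season):
        data, _ = ushape_season
        cmp_ = compare_models(fit_model(data, DesignSpec("linear")),
                              fit_model(data, DesignSpec("nonlinear")))
        assert cmp_.p < 0.01 and cmp_.aic_nonlinear < cmp_.aic_linear

    def test_ill_posed_criteria_rejected(self, ols_points):
        weeks, cadence = ols_points
        fit = fit_model(_frame(weeks, cadence), DesignSpec("linear", random_effects=()))
        with pytest.raises(IllPosedCriteriaError):
            model_criteria(fit, n_obs=2)


class TestPrediction:
    def test_flat_noise_free_curve_is_constant_with_season_offset(self):
        cfg = SeasonGenConfig(n_participants=4, weeks=tuple(range(8)), trend_shape="flat",
                              beta0=60.0, beta2=2.5, two_season_fraction=0.5, sd_eps=0.0,
                              seed=0)
        data, _ = gen_season_dataset(cfg)
        fit = fit_model(data, DesignSpec("linear"))
        grid = np.arange(8.0)
        c1 = predict_curve(fit, grid, season=1)
        c2 = predict_curve(fit, grid, season=2)
        np.testing.assert_allclose(c1.mean, 60.0, atol=1e-6)
        np.testing.assert_allclose(c2.mean, 62.5, atol=1e-6)
        assert np.all(c1.lo95 <= c1.mean) and np.all(c1.mean <= c1.hi95)

    def test_ci_wider_where_data_are_sparse(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(8):
            pid = f"P{i:02d}"
            weeks = list(range(0, 11)) + ([14] if i < 2 else [])
            for w in weeks:
                rows.append({"participant_id": pid, "week": float(w), "season": 1,
                             "cadence": 60.0 + 0.2 * w + rng.normal(0, 1.5)})
        data = pd.DataFrame(rows)
        fit = fit_model(data, DesignSpec("nonlinear"))
        curve = predict_curve(fit, np.array([5.0, 14.0]))
        dense_hw = curve.hi95[0] - curve.lo95[0]
        sparse_hw = curve.hi95[1] - curve.lo95[1]
        assert sparse_hw > dense_hw

    def test_individual_level_adds_participant_effects(self, linear_season):
        data, _ = linear_season
        fit = fit_model(data, DesignSpec("linear"))
        grid = np.arange(12.0)
        curve = predict_curve(fit, grid, level="individual")
        pid = fit._state.participants[0]
        expected = curve.mean + fit.b0[pid] + fit.b1[pid] * grid
        np.testing.assert_allclose(curve.individual[pid].to_numpy(), expected, atol=1e-10)

    def test_extrapolation_flagged_not_rejected(self, linear_season):
        data, _ = linear_season
        fit = fit_model(data, DesignSpec("linear"))
        curve = predict_curve(fit, np.array([5.0, 20.0]))
        assert list(curve.extrapolated) == [False, True]


class TestWeeklyPercentChange:
    def test_constant_curve_changes_nothing(self):
        c = PredictionCurve(weeks=np.arange(5.0), mean=np.full(5, 80.0),
                            lo95=np.full(5, 79.0), hi95=np.full(5, 81.0))
        pct, mean = weekly_percent_change(c)
        np.testing.assert_allclose(pct, 0.0)
        assert mean == 0.0

    def test_worked_example(self):
        c = PredictionCurve(weeks=np.arange(3.0), mean=np.array([100.0, 102.0, 99.0]),
                            lo95=np.zeros(3), hi95=np.zeros(3))
        pct, mean = weekly_percent_change(c)
        np.testing.assert_allclose(pct, [2.0, -2.9411764705882355], atol=1e-10)
        assert mean == pytest.approx(-0.47058823529411764, abs=1e-10)

    def test_non_unit_grid_rejected(self):
        c = PredictionCurve(weeks=np.array([0.0, 2.0, 4.0]), mean=np.ones(3),
                            lo95=np.zeros(3), hi95=np.zeros(3))
        with pytest.raises(ValueError):
            weekly_percent_change(c)
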