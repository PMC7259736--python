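"""Prediction curves, threshold interpolation and comparator models."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from nutcracker_occupancy.occupancy_mcmc import PosteriorDraws
from nutcracker_occupancy.prediction_comparison import (
    PredictionCurve,
    barringer_predict,
    compare_observed_predicted,
    comparator_filter,
    cone_production_index,
    mckinney_predict,
    predict_psi,
    threshold_area,
)


def hand_draws(alpha_draws, beta_draws, covariate="area", mu=0.0, sd=1.0, rng=(0.0, 10.0)):
    """Single-stage, single-covariate posterior with explicit draw values."""
    a = np.asarray(alpha_draws, dtype=float)[None, :, None]
    b = np.asarray(beta_draws, dtype=float)[None, :, None, None]
    meta = {
        "stage_names": ["fall_harvest"],
        "columns": [covariate],
        "terms": {covariate: [covariate]},
        "column_stats": {covariate: [mu, sd]},
        "observed_range": {covariate: list(rng)},
    }
    return PosteriorDraws(
        params={"alpha": a, "beta": b, "mu_p": np.zeros((1, a.shape[1]))},
        coords={},
        meta=meta,
    )


class TestPredictPsi:
    def test_zero_coefficients_give_flat_curve(self):
        d = hand_draws([logit(0.7)] * 8, [0.0] * 8)
        curve = predict_psi(d, "fall_harvest", "area", grid=np.linspace(0, 10, 5))
        np.testing.assert_allclose(curve.mean, 0.7, atol=1e-12)
        np.testing.assert_allclose(curve.lower95, 0.7, atol=1e-12)

    def test_positive_coefficients_give_monotone_curve(self):
        rng = np.random.default_rng(0)
        d = hand_draws(rng.normal(0, 1, 50), rng.uniform(0.2, 2.0, 50))
        curve = predict_psi(d, "fall_harvest", "area", grid=np.linspace(0, 10, 30))
        assert (np.diff(curve.mean) >= 0).all()

    def test_four_draw_percentiles_match_enumeration(self):
        alphas = [-1.0, 0.0, 0.5, 2.0]
        betas = [0.5, 1.0, -0.3, 0.2]
        grid = np.array([2.0, 5.0, 8.0])
        mu, sd = 5.0, 2.0
        d = hand_draws(alphas, betas, mu=mu, sd=sd)
        curve = predict_psi(d, "fall_harvest", "area", grid=grid)
        # direct enumeration of the four curves
        for g_i, g in enumerate(grid):
            values = [
                1.0 / (1.0 + math.exp(-(a + b * (g - mu) / sd)))
                for a, b in zip(alphas, betas)
            ]
            assert curve.mean[g_i] == pytest.approx(np.mean(values), abs=1e-12)
            lo, hi = np.percentile(values, [2.5, 97.5])
            assert curve.lower95[g_i] == pytest.approx(lo, abs=1e-12)
            assert curve.upper95[g_i] == pytest.approx(hi, abs=1e-12)

    def test_standardization_invariance_of_mean_curve(self):
        # one data-scale model (logit psi = a0 + s*g) expressed under two
        # standardizations must yield identical curves on the original grid
        a0_draws = np.array([0.1, 0.4, -0.2, 0.6])
        slopes = np.array([0.3, 0.25, 0.35, 0.3])  # per original unit
        grid = np.linspace(0.0, 10.0, 7)
        curves = []
        for mu, sd in ((5.0, 2.0), (2.0, 4.0)):
            d = hand_draws(a0_draws + slopes * mu, slopes * sd, mu=mu, sd=sd)
            curves.append(predict_psi(d, "fall_harvest", "area", grid=grid).mean)
        np.testing.assert_allclose(curves[0], curves[1], atol=1e-12)

    def test_unknown_conditioning_covariate_rejected(self):
        d = hand_draws([0.0], [0.0])
        with pytest.raises(KeyError):
            predict_psi(
                d, "fall_harvest", "area", grid=np.array([1.0]),
                conditioning={"ghost": 1.0},
            )

    def test_extrapolation_flagged(self):
        d = hand_draws([0.0] * 4, [0.1] * 4, rng=(0.0, 10.0))
        with pytest.warns(UserWarning, match="beyond the observed"):
            curve = predict_psi(
                d, "fall_harvest", "area", grid=np.array([5.0, 50.0])
            )
        assert curve.extrapolated.tolist() == [False, True]


def flat_curve(mean_values, grid):
    m = np.asarray(mean_values, dtype=float)
    return PredictionCurve(
        covariate="area",
        grid=np.asarray(grid, dtype=float),
        grid_standardized=np.asarray(grid, dtype=float),
        mean=m,
        lower95=m - 0.05,
        upper95=m + 0.05,
        stage="fall_harvest",
        conditioning={},
        extrapolated=np.zeros(len(m), dtype=bool),
    )


class TestThreshold:
    def test_unreachable_target_returns_none(self):
        assert threshold_area(flat_curve([0.5, 0.5, 0.5], [0, 1, 2]), 0.75) is None

    def test_already_above_target_returns_grid_minimum(self):
        assert threshold_area(flat_curve([0.8, 0.9], [100, 200]), 0.75) == 100.0

    def test_linear_interpolation(self):
        curve = flat_curve([0.6, 0.8], [10_000, 20_000])
        assert threshold_area(curve, 0.75) == pytest.approx(17_500.0)

    def test_monotone_in_target(self):
        curve = flat_curve([0.2, 0.5, 0.7, 0.9], [0, 1, 2, 3])
        t1 = threshold_area(curve, 0.4)
        t2 = threshold_area(curve, 0.8)
        assert t1 < t2

    def test_multimodal_curve_warns(self):
        curve = flat_curve([0.8, 0.5, 0.9], [0, 1, 2])
        with pytest.warns(UserWarning, match="more than once"):
            assert threshold_area(curve, 0.75) == 0.0

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            threshold_area(flat_curve([0.5], [0]), 1.5)


class TestComparatorModels:
    def test_mckinney_intercept(self):
        assert mckinney_predict(0.0) == pytest.approx(-0.449)

    def test_mckinney_root(self):
        root = 0.449 / 0.019
        assert mckinney_predict(root) == pytest.approx(0.0, abs=1e-12)

    def test_mckinney_unclipped_beyond_one(self):
        assert mckinney_predict(100.0) == pytest.approx(1.451)

    def test_mckinney_affine_slope(self):
        x = np.linspace(0, 50, 11)
        np.testing.assert_allclose(np.diff(mckinney_predict(x)) / np.diff(x), 0.019)

    def test_barringer_intercept(self):
        assert barringer_predict(0.0) == pytest.approx(
            1.0 / (1.0 + math.exp(1.5165)), abs=1e-12
        )

    def test_barringer_saturates_toward_one(self):
        assert barringer_predict(300.0) > 0.999

    def test_barringer_strictly_increasing_within_unit_interval(self):
        x = np.linspace(0, 200, 500)
        y = barringer_predict(x)
        assert (np.diff(y) > 0).all()
        assert ((y > 0) & (y < 1)).all()

    def test_cone_production_index(self):
        np.testing.assert_allclose(
            cone_production_index([math.e**2]), [4.0], atol=1e-12
        )
        np.testing.assert_allclose(
            cone_production_index([100.0], base="log10"), [4.0], atol=1e-12
        )
        with pytest.raises(ValueError):
            cone_production_index([0.0])


class TestComparison:
    def test_identical_vectors(self):
        x = np.array([0.0, 1 / 3, 2 / 3, 1.0, 1 / 3, 0.0])
        res = compare_observed_predicted(x, x.copy())
        assert res["spearman_rho"] == pytest.approx(1.0)
        assert np.isnan(res["wilcoxon_w"])

    def test_strict_underprediction_small_p(self):
        rng = np.random.default_rng(0)
        predicted = rng.uniform(0.1, 0.4, 10)
        observed = predicted + rng.uniform(0.05, 0.3, 10)
        res = compare_observed_predicted(observed, predicted)
        # all 10 differences positive: W = 55, exact one-tailed p = 2^-10
        assert res["wilcoxon_w"] == pytest.approx(55.0)
        assert res["wilcoxon_p"] < 0.01

    def test_anti_monotone_rho(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pred = obs[::-1].copy()
        res = compare_observed_predicted(obs, pred)
        assert res["spearman_rho"] == pytest.approx(-1.0)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            compare_observed_predicted(np.ones(3), np.zeros(3))


class TestComparatorFilter:
    def test_filters_radius_cones_and_dates(self):
        units = pd.DataFrame(
            {
                "radius_class": ["infinite", "infinite", "within_100m", "infinite"],
                "cone_density": [100.0, 0.0, 100.0, 50.0],
                "date": ["2011-08-01", "2011-08-01", "2011-08-01", "2011-10-01"],
            }
        )
        kept = comparator_filter(units)
        assert kept.index.tolist() == [0]

    def test_window_boundaries_inclusive(self):
        units = pd.DataFrame(
            {
                "radius_class": ["infinite"] * 2,
                "cone_density": [10.0, 10.0],
                "date": ["2011-07-15", "2011-09-15"],
            }
        )
        assert len(comparator_filter(units)) == 2
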