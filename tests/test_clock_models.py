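import datetime as dt
import math

import numpy as np
import pytest
from scipy import optimize

from evoclock.clock_models import (
    aicc,
    analyze_series,
    fit_mean,
    fit_variance_challenging,
    fit_variance_null,
    rescale_variance,
    select_model,
)
from evoclock.errors import DegenerateInputError, InsufficientDataError
from evoclock.stats_binning import BinnedSeries, TimeBinStats

ORIGIN = dt.date(2021, 1, 1)


def series_from(mus=None, sigma2s=None, weights=None, n=50):
    """Hand-build a BinnedSeries with prescribed per-bin statistics."""
    k_count = len(mus) if mus is not None else len(sigma2s)
    mus = mus if mus is not None else [0.0] * k_count
    sigma2s = sigma2s if sigma2s is not None else [0.0] * k_count
    weights = weights if weights is not None else [math.tanh(n / 15)] * k_count
    bins = [
        TimeBinStats(k=k, t=float(k), n=n, mu=mus[k], sigma2=sigma2s[k], w=weights[k])
        for k in range(k_count)
    ]
    return BinnedSeries(category="total", origin_date=ORIGIN, interval_days=7, bins=bins)


# ------------------------------- mean fit ----------------------------------

class TestFitMean:
    def test_exact_line_recovered(self):
        fit = fit_mean(series_from(mus=[0.0, 0.5, 1.0]))
        assert fit.kappa == pytest.approx(0.5, abs=1e-12)
        assert fit.m0 == pytest.approx(0.0, abs=1e-12)

    def test_constant_means_zero_slope(self):
        fit = fit_mean(series_from(mus=[2.5, 2.5, 2.5, 2.5]))
        assert fit.kappa == pytest.approx(0.0, abs=1e-12)
        assert fit.m0 == pytest.approx(2.5, abs=1e-12)

    def test_matches_closed_form_weighted_least_squares(self):
        rng = np.random.default_rng(42)
        mus = list(0.3 * np.arange(6) + rng.normal(0, 0.2, 6))
        weights = list(rng.uniform(0.3, 1.0, 6))
        fit = fit_mean(series_from(mus=mus, weights=weights))
        t = np.arange(6.0)
        w = np.array(weights)
        y = np.array(mus)
        sw, swt, swt2 = w.sum(), (w * t).sum(), (w * t * t).sum()
        swy, swty = (w * y).sum(), (w * t * y).sum()
        det = sw * swt2 - swt**2
        slope = (sw * swty - swt * swy) / det
        intercept = (swt2 * swy - swt * swty) / det
        assert fit.kappa == pytest.approx(slope, abs=1e-10)
        assert fit.m0 == pytest.approx(intercept, abs=1e-10)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_mean(series_from(mus=[0.0, 1.0]))

    def test_ci_is_symmetric_and_covers_estimate(self):
        rng = np.random.default_rng(7)
        fit = fit_mean(series_from(mus=list(0.5 * np.arange(8) + rng.normal(0, 0.1, 8))))
        assert fit.kappa_ci.lower < fit.kappa < fit.kappa_ci.upper
        mid = (fit.kappa_ci.lower + fit.kappa_ci.upper) / 2
        assert mid == pytest.approx(fit.kappa, abs=1e-10)


# --------------------------- variance rescaling ----------------------------

class TestRescaleVariance:
    def test_subtracts_initial_variance_and_shifts_time(self):
        rv = rescale_variance(series_from(sigma2s=[2.0, 3.0, 4.0]))
        assert rv.pairs() == [(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)]
        assert rv.sigma2_0 == 2.0

    def test_zero_initial_variance_unchanged(self):
        rv = rescale_variance(series_from(sigma2s=[0.0, 1.0, 2.0]))
        assert rv.pairs() == [(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)]

    def test_negative_rescaled_values_retained(self):
        rv = rescale_variance(series_from(sigma2s=[4.0, 3.0, 5.0]))
        assert rv.pairs() == [(0.0, 0.0), (1.0, -1.0), (2.0, 1.0)]

    def test_initial_variance_from_earliest_variance_bin(self):
        # first bin has a single sample: variance undefined there
        bins = [
            TimeBinStats(k=0, t=0.0, n=1, mu=1.0, sigma2=None, w=math.tanh(1 / 15)),
            TimeBinStats(k=1, t=1.0, n=20, mu=1.5, sigma2=2.0, w=math.tanh(20 / 15)),
            TimeBinStats(k=2, t=2.0, n=20, mu=2.0, sigma2=3.0, w=math.tanh(20 / 15)),
            TimeBinStats(k=3, t=3.0, n=20, mu=2.5, sigma2=4.5, w=math.tanh(20 / 15)),
        ]
        series = BinnedSeries("total", ORIGIN, 7, bins)
        rv = rescale_variance(series)
        assert rv.sigma2_0 == 2.0 and rv.t0 == 1.0
        assert rv.pairs()[0] == (0.0, 0.0)


# ----------------------------- variance fits -------------------------------

class TestFitVarianceNull:
    def test_exact_proportionality(self):
        fit = fit_variance_null(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]),
                                np.ones(3))
        assert fit.D == pytest.approx(1.0, abs=1e-12)
        assert fit.rss_weighted == pytest.approx(0.0, abs=1e-20)

    def test_closed_form_weighted_through_origin_slope(self):
        rng = np.random.default_rng(3)
        t = np.arange(1.0, 9.0)
        y = 2.0 * t + rng.normal(0, 0.5, 8)
        w = rng.uniform(0.2, 1.0, 8)
        fit = fit_variance_null(t, y, w)
        assert fit.D == pytest.approx(np.sum(w * t * y) / np.sum(w * t * t), abs=1e-10)
        assert fit.rss_weighted == pytest.approx(
            np.sum(w * (y - fit.D * t) ** 2), abs=1e-10
        )

    def test_two_point_slope(self):
        fit = fit_variance_null(np.array([1.0, 2.0]), np.array([2.0, 4.0]), np.ones(2))
        assert fit.D == pytest.approx(2.0, abs=1e-12)

    def test_all_zero_times_degenerate(self):
        with pytest.raises(DegenerateInputError):
            fit_variance_null(np.zeros(3), np.ones(3), np.ones(3))


class TestFitVarianceChallenging:
    def test_noiseless_square_root_recovered(self):
        t = np.array([1.0, 4.0, 9.0])
        fit = fit_variance_challenging(t, np.sqrt(t), np.ones(3))
        assert fit.D == pytest.approx(1.0, abs=1e-6)
        assert fit.alpha == pytest.approx(0.5, abs=1e-6)

    def test_noiseless_linear_degenerates_to_line(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_variance_challenging(t, 2.0 * t, np.ones(4))
        assert fit.D == pytest.approx(2.0, abs=1e-6)
        assert fit.alpha == pytest.approx(1.0, abs=1e-6)

    def test_alpha_fixed_at_one_reproduces_null_slope(self):
        rng = np.random.default_rng(11)
        t = np.arange(1.0, 12.0)
        y = 1.3 * t + rng.normal(0, 0.8, t.size)
        w = rng.uniform(0.5, 1.0, t.size)
        null = fit_variance_null(t, y, w)
        # one-parameter power law with alpha pinned to 1, fitted independently
        popt, _ = optimize.curve_fit(
            lambda tt, D: D * tt, t, y, p0=[1.0], sigma=1 / np.sqrt(w),
            absolute_sigma=False,
        )
        assert popt[0] == pytest.approx(null.D, abs=1e-6)

    def test_zero_or_negative_times_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_variance_challenging(np.array([0.0, 1, 2]), np.ones(3), np.ones(3))


# --------------------------------- AICc ------------------------------------

class TestAicc:
    def test_hand_evaluated_value(self):
        # 10 ln(2 pi) + 10 ln(1) + 10 + 2 + 2*1*2/(10-1-1)
        assert aicc(10.0, 10, 1) == pytest.approx(30.8788, abs=5e-5)

    def test_penalty_monotone_in_parameter_count(self):
        for n in (5, 10, 50):
            assert aicc(3.0, n, 2) > aicc(3.0, n, 1)

    def test_boundary_degrees_of_freedom(self):
        assert math.isfinite(aicc(1.0, 4, 2))
        with pytest.raises(InsufficientDataError):
            aicc(1.0, 3, 2)

    def test_perfect_fit_sentinel(self):
        assert aicc(0.0, 10, 1) == -math.inf


# ----------------------------- model selection -----------------------------

def analysis_for(sigma2s, mus=None, n=50):
    k = len(sigma2s)
    mus = mus if mus is not None else list(0.5 * np.arange(k))
    return analyze_series(series_from(mus=mus, sigma2s=sigma2s, n=n))


class TestSelection:
    def test_linear_variance_selects_null(self):
        rng = np.random.default_rng(0)
        sigma2s = list(np.arange(15.0) + rng.normal(0, 0.3, 15))
        result = analysis_for(sigma2s).selection
        assert result.selected == "null"
        assert result.delta_aicc >= 0

    def test_subdiffusive_variance_selects_challenging(self):
        t = np.arange(15.0)
        rng = np.random.default_rng(1)
        sigma2s = list(np.sqrt(t) + rng.normal(0, 0.05, 15))
        result = analysis_for(sigma2s).selection
        assert result.selected == "challenging"
        assert result.challenging_fit.params.alpha == pytest.approx(0.5, abs=0.1)

    def test_both_fits_share_point_count(self):
        rng = np.random.default_rng(2)
        sigma2s = list(np.arange(12.0) + rng.normal(0, 0.5, 12))
        sel = analysis_for(sigma2s).selection
        assert sel.null_fit.n == sel.challenging_fit.n

    def test_mismatched_point_sets_rejected(self):
        rng = np.random.default_rng(3)
        a = analysis_for(list(np.arange(12.0) + rng.normal(0, 0.4, 12))).selection
        b = analysis_for(list(np.arange(10.0) + rng.normal(0, 0.4, 10))).selection
        with pytest.raises(DegenerateInputError):
            select_model(a.null_fit, b.challenging_fit)

    def test_exact_tie_resolved_to_null(self):
        sel = analysis_for(list(np.arange(10.0)))
        # noiseless linear data: both models fit perfectly (RSS=0, AICc=-inf)
        assert sel.selection.selected == "null"

    def test_ci_width_shrinks_with_more_bins(self):
        rng = np.random.default_rng(9)
        noise = rng.normal(0, 0.2, 40)
        small = analysis_for(
            list(np.arange(8.0) + noise[:8]), mus=list(0.5 * np.arange(8) + noise[:8])
        )
        large = analysis_for(
            list(np.arange(40.0) + noise), mus=list(0.5 * np.arange(40) + noise)
        )
        width = lambda ci: ci.upper - ci.lower
        assert width(large.mean_fit.kappa_ci) < width(small.mean_fit.kappa_ci)
        assert width(large.selection.null_fit.cis["D"]) < width(
            small.selection.null_fit.cis["D"]
        )
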