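import numpy as np
import pytest
from scipy.stats import norm

from sgem import (
    Ensemble,
    SGEMParams,
    TimeGrid,
    analytic_median_x,
    calibrate_alpha_for_median,
    ensemble_mean,
    marginal_at,
    pointwise_percentiles,
    simulate_ensemble,
)
from sgem.errors import (
    CalibrationError,
    InvalidInputError,
    InvalidProtocolError,
    RangeError,
    UnsupportedParameterError,
)
from sgem.stochastic import (
    member_seed_sequence,
    power_exponential_transform,
    simulate_wiener,
)


def constant_ensemble(levels, grid=None):
    grid = grid or TimeGrid(4.0, 1.0)
    values = np.tile(np.asarray(levels)[:, None], (1, len(grid)))
    return Ensemble(SGEMParams(), grid, values, seed=0)


class TestSimulateEnsemble:
    def test_alpha_zero_all_members_full(self):
        e = simulate_ensemble(SGEMParams(0.0, 6), n=10, t_end=5.0, dt=0.5, seed=0)
        assert np.all(e.values == 1.0)

    def test_determinism(self, default_params):
        a = simulate_ensemble(default_params, n=5, t_end=5.0, dt=0.5, seed=42)
        b = simulate_ensemble(default_params, n=5, t_end=5.0, dt=0.5, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_members_are_distinct_substreams(self, default_params):
        e = simulate_ensemble(default_params, n=4, t_end=60.0, dt=0.1, seed=0)
        assert len({tuple(row) for row in e.values}) == 4

    def test_empty_ensemble_rejected(self, default_params):
        with pytest.raises(InvalidProtocolError):
            simulate_ensemble(default_params, n=0)

    def test_member_invariants(self, small_ensemble):
        v = small_ensemble.values
        assert np.all(v[:, 0] == 1.0)
        assert np.all(v >= 0.0) and np.all(v <= 1.0)
        assert np.all(np.diff(v, axis=1) <= 0.0)


class TestPointwisePercentiles:
    def test_middle_order_statistic(self):
        e = constant_ensemble([0.2, 0.5, 0.8])
        bands = pointwise_percentiles(e, (50.0,))
        assert np.all(bands.curve(50.0) == 0.5)

    def test_degenerate_distribution(self):
        e = constant_ensemble([0.3, 0.3, 0.3])
        bands = pointwise_percentiles(e, (5.0, 95.0))
        assert np.all(bands.curves == 0.3)

    def test_band_ordering(self, small_ensemble):
        bands = pointwise_percentiles(small_ensemble, (5.0, 25.0, 50.0, 75.0, 95.0))
        assert np.all(np.diff(bands.curves, axis=0) >= 0)

    def test_matches_sort_based_oracle(self, small_ensemble):
        bands = pointwise_percentiles(small_ensemble, (5.0, 95.0))
        idx = np.linspace(0, small_ensemble.values.shape[1] - 1, 10).astype(int)
        for j in idx:
            col = np.sort(small_ensemble.values[:, j])
            n = len(col)
            for p, curve in zip(bands.probs, bands.curves):
                h = (n - 1) * p / 100.0
                lo, frac = int(np.floor(h)), h - np.floor(h)
                expect = col[lo] + frac * (col[min(lo + 1, n - 1)] - col[lo])
                assert curve[j] == pytest.approx(expect, abs=1e-14)

    def test_reproducible_bands(self, default_params):
        a = simulate_ensemble(default_params, n=50, t_end=20.0, dt=0.1, seed=5)
        b = simulate_ensemble(default_params, n=50, t_end=20.0, dt=0.1, seed=5)
        assert np.array_equal(
            pointwise_percentiles(a).curves, pointwise_percentiles(b).curves
        )

    @pytest.mark.parametrize("probs", [(), (0.0, 95.0), (5.0, 100.0), (-1.0,)])
    def test_bad_levels_rejected(self, small_ensemble, probs):
        with pytest.raises(InvalidInputError):
            pointwise_percentiles(small_ensemble, probs)


class TestEnsembleMean:
    def test_single_member_is_itself(self, default_params):
        e = simulate_ensemble(default_params, n=1, t_end=10.0, dt=0.1, seed=3)
        assert np.array_equal(ensemble_mean(e), e.values[0])

    def test_mean_within_pointwise_range(self, small_ensemble):
        m = ensemble_mean(small_ensemble)
        assert np.all(m >= small_ensemble.values.min(axis=0) - 1e-15)
        assert np.all(m <= small_ensemble.values.max(axis=0) + 1e-15)

    def test_mean_mostly_inside_wide_central_band(self, small_ensemble):
        bands = pointwise_percentiles(small_ensemble, (5.0, 95.0))
        m = ensemble_mean(small_ensemble)
        inside = (m >= bands.curves[0]) & (m <= bands.curves[1])
        assert inside.mean() >= 0.95


class TestMarginalAt:
    def test_time_zero_is_all_ones(self, small_ensemble):
        assert np.all(marginal_at(small_ensemble, 0.0) == 1.0)

    def test_out_of_range_rejected(self, small_ensemble):
        with pytest.raises(RangeError):
            marginal_at(small_ensemble, 1e9)

    def test_median_below_median_of_x(self, default_params):
        # S <= X pathwise, so the order carries over to medians
        t_star, n, dt = 60.0, 100, 0.1
        e = simulate_ensemble(default_params, n=n, t_end=120.0, dt=dt, seed=0)
        x_at = np.empty(n)
        for i in range(n):
            w = simulate_wiener(120.0, dt, member_seed_sequence(0, i))
            x = power_exponential_transform(w, default_params)
            x_at[i] = x.values[e.grid.index_at_or_before(t_star)]
        assert np.median(marginal_at(e, t_star)) <= np.median(x_at) + 1e-15


class TestAnalyticMedianX:
    def test_alpha_zero_is_one(self):
        assert analytic_median_x(100.0, SGEMParams(0.0, 6)) == 1.0

    def test_closed_form_against_gaussian_quantile(self):
        # median of |W(1)| is the 75th-percentile point of the standard normal
        m = norm.ppf(0.75)
        got = analytic_median_x(1.0, SGEMParams(1.0, 2))
        assert got == pytest.approx(np.exp(-(m**2)), rel=1e-9)
        assert got == pytest.approx(np.exp(-0.45493642), abs=1e-7)

    def test_odd_beta_unsupported(self):
        with pytest.raises(UnsupportedParameterError):
            analytic_median_x(10.0, SGEMParams(1e-6, 3))

    def test_monte_carlo_agreement_small_scale(self, default_params):
        # loose small-n check; the full-protocol check lives in the acceptance suite
        n, t_star = 400, 150.0
        vals = np.empty(n)
        for i in range(n):
            w = simulate_wiener(t_star, 0.05, member_seed_sequence(17, i))
            vals[i] = np.exp(-default_params.alpha * w.values[-1] ** default_params.beta)
        expect = analytic_median_x(t_star, default_params)
        assert np.median(vals) == pytest.approx(expect, abs=0.1)


class TestCalibration:
    def test_target_one_returns_zero_alpha(self):
        assert calibrate_alpha_for_median(6, target_median=1.0, n=10, dt=1.0) == 0.0

    def test_alpha_non_increasing_in_target(self):
        kw = dict(t_star=60.0, n=100, t_end=120.0, dt=0.5, seed=0, tol=1e-4)
        alphas = [
            calibrate_alpha_for_median(6, target_median=tm, **kw)
            for tm in (0.3, 0.5, 0.7, 0.9)
        ]
        assert all(a >= b - 1e-18 for a, b in zip(alphas, alphas[1:]))

    def test_self_consistency_under_resampling(self):
        alpha = calibrate_alpha_for_median(
            6, t_star=60.0, target_median=0.5, n=300, t_end=120.0, dt=0.1, seed=0
        )
        e = simulate_ensemble(SGEMParams(alpha, 6), n=300, t_end=120.0, dt=0.1, seed=99)
        med = np.median(marginal_at(e, 60.0))
        assert med == pytest.approx(0.5, abs=0.1)

    def test_odd_beta_rejected(self):
        with pytest.raises(UnsupportedParameterError):
            calibrate_alpha_for_median(3, n=10, dt=1.0)

    def test_unreachable_target_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_alpha_for_median(
                6, t_star=60.0, target_median=0.5, n=50, t_end=120.0, dt=0.5,
                alpha_bracket=(1e-12, 1e-11),
            )

    def test_bad_target_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_alpha_for_median(6, target_median=0.0, n=10, dt=1.0)
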