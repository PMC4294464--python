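"""Grey Verhulst model: sequence operators, least-squares fit, time response."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import greyshap as gs
from greyshap.grey_verhulst import (
    Orientation,
    ago,
    fit,
    forecast,
    iago,
    mean_sequence,
    time_response,
)

# differenced fatality sequence and neighbour means of the study series
STUDY_DIFFS = [109381, -5009, -5155, -479, -9283, -7806, -8165, -6325, -1934, -2838]
STUDY_MEANS = [106876.5, 101794.5, 98977.5, 94096.5, 85552.0,
               77566.5, 70321.5, 66192.0, 63806.0]

finite_values = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=2, max_size=30
)


class TestSequenceOperators:
    def test_iago_of_study_series(self, table1):
        assert iago(table1).values.tolist() == STUDY_DIFFS

    def test_iago_of_constant_series(self):
        s = gs.AnnualSeries([2000, 2001, 2002], [7.0, 7.0, 7.0])
        assert iago(s).values.tolist() == [7.0, 0.0, 0.0]

    def test_iago_requires_two_points(self):
        with pytest.raises(gs.ValidationError):
            iago(gs.AnnualSeries([2000], [1.0]))

    @given(finite_values)
    @settings(max_examples=100, deadline=None)
    def test_ago_iago_are_exact_inverses(self, values):
        series = gs.AnnualSeries(2000 + np.arange(len(values)), ago(values))
        assert iago(series).values == pytest.approx(values, abs=1e-6)
        # and the other composition restores the series itself
        assert iago(series).accumulate() == pytest.approx(series.values)

    def test_mean_sequence_of_study_series(self, table1):
        assert mean_sequence(table1).values.tolist() == STUDY_MEANS

    @pytest.mark.parametrize("values,expected", [([2.0, 4.0], [3.0]), ([5.0, 5.0], [5.0])])
    def test_mean_sequence_small_cases(self, values, expected):
        s = gs.AnnualSeries(2000 + np.arange(len(values)), values)
        assert mean_sequence(s).values.tolist() == expected

    @given(finite_values)
    @settings(max_examples=100, deadline=None)
    def test_mean_lies_between_neighbours(self, values):
        s = gs.AnnualSeries(2000 + np.arange(len(values)), values)
        z = mean_sequence(s).values
        lo = np.minimum(s.values[1:], s.values[:-1])
        hi = np.maximum(s.values[1:], s.values[:-1])
        assert np.all(z >= lo) and np.all(z <= hi)


class TestFit:
    def test_study_parameters(self, verhulst_fit):
        assert verhulst_fit.a == pytest.approx(0.12238288, abs=5e-9)
        assert verhulst_fit.mu == pytest.approx(0.00000069, abs=5e-9)
        assert verhulst_fit.anchor == 109381.0

    def test_fitted_reproduces_study_table(self, verhulst_fit):
        printed = gs.load_fixture("table2_printed")
        assert np.all(np.abs(verhulst_fit.fitted.rounded() - printed["predicted"]) <= 1)

    def test_least_squares_beats_local_grid(self, table1, verhulst_fit):
        """Brute-force check: no (a, mu) on a fine local grid has lower SSE."""
        z = np.asarray(STUDY_MEANS)
        x0 = np.asarray(STUDY_DIFFS[1:], dtype=float)

        def sse(a, mu):
            return np.sum((x0 + a * z - mu * z**2) ** 2)

        best = sse(verhulst_fit.a, verhulst_fit.mu)
        a_grid = verhulst_fit.a * (1 + np.linspace(-0.01, 0.01, 41))
        mu_grid = verhulst_fit.mu * (1 + np.linspace(-0.01, 0.01, 41))
        grid = np.array([sse(a, m) for a in a_grid for m in mu_grid])
        assert best <= grid.min() + 1e-9 * abs(grid.min())

    @pytest.mark.parametrize("a_true", [0.05, 0.08, 0.12, 0.15])
    def test_parameter_recovery_on_noise_free_logistic(self, a_true):
        """Discretization bias stays below 1% for moderate decay rates."""
        spec = gs.LogisticSpec(a=a_true, mu=a_true / 180000, x0=109381, n=12, noise=0.0)
        refit = fit(gs.generate_logistic(spec))
        assert refit.a == pytest.approx(a_true, rel=0.01)
        assert refit.mu == pytest.approx(spec.mu, rel=0.01)

    @pytest.mark.parametrize("a_true", [0.05, 0.1, 0.15, 0.2, 0.25, 0.3])
    def test_refit_errors_below_one_percent_on_noise_free_input(self, a_true):
        spec = gs.LogisticSpec(a=a_true, mu=a_true / 150000, x0=120000, n=10, noise=0.0)
        series = gs.generate_logistic(spec)
        refit = fit(series)
        rel = np.abs(series.values - refit.fitted.values) / series.values * 100
        assert rel.max() < 1.0

    def test_minimum_length_series_fits(self):
        series = gs.AnnualSeries([2000, 2001, 2002, 2003], [100.0, 90.0, 82.0, 76.0])
        result = fit(series)
        assert np.isfinite([result.a, result.mu]).all()
        report = gs.relative_errors(series, result.fitted)
        assert np.isfinite(report.relative_errors).all()

    def test_constant_series_is_degenerate(self):
        series = gs.AnnualSeries(range(2000, 2006), [50.0] * 6)
        with pytest.raises(gs.DegenerateFitError):
            fit(series)

    def test_classic_ago_matches_fit_on_accumulated_series(self):
        """Fitting the differences under classic AGO equals fitting the
        accumulated curve directly, since cumulative summation restores it."""
        # increasing saturating cumulative curve (negative decay rate)
        t = np.arange(10.0)
        x1 = 1e5 / (1.0 + 9.0 * np.exp(-0.4 * t))
        years = 2000 + np.arange(10)
        diffs = np.concatenate(([x1[0]], np.diff(x1)))
        assert np.all(diffs > 0)
        classic = fit(gs.AnnualSeries(years, diffs), orientation="classic")
        direct = fit(gs.AnnualSeries(years, x1), orientation="paper")
        assert classic.a == pytest.approx(direct.a, rel=1e-12)
        assert classic.mu == pytest.approx(direct.mu, rel=1e-12)
        # classic fitted values live in the observed (differenced) scale
        assert classic.fitted.values[1:] == pytest.approx(
            np.diff(direct.fitted.values), rel=1e-12
        )

    def test_orientation_aliases(self, table1):
        assert fit(table1, "paper").a == fit(table1, "observed_as_accumulated").a


class TestTimeResponseAndForecast:
    def test_anchor_year_exact(self, verhulst_fit):
        assert time_response(verhulst_fit, 0) == pytest.approx(109381, abs=1e-9)

    @pytest.mark.parametrize("k,expected", [(1, 104176), (9, 61769)])
    def test_study_fitted_values(self, verhulst_fit, k, expected):
        assert round(time_response(verhulst_fit, k)) == expected

    @given(
        a=st.floats(min_value=0.01, max_value=0.5),
        saturation=st.floats(min_value=1e3, max_value=1e6),
    )
    @settings(max_examples=50, deadline=None)
    def test_anchor_exact_for_any_parameters(self, a, saturation):
        spec = gs.LogisticSpec(a=a, mu=a / saturation, x0=5e4, n=6)
        refit_input = gs.generate_logistic(spec)
        f = gs.grey_verhulst.GreyVerhulstFit(
            a=a, mu=a / saturation, anchor=refit_input.values[0],
            orientation=Orientation.OBSERVED_AS_ACCUMULATED,
            fitted=refit_input, n=6,
        )
        assert time_response(f, 0) == pytest.approx(f.anchor, rel=1e-12)

    def test_first_out_of_sample_year(self, verhulst_fit):
        future = forecast(verhulst_fit, 2)
        assert future.first_year == 2012
        assert round(future.values[0]) == 56936  # continuation index k = 10

    def test_forecast_declines_monotonically(self, verhulst_fit):
        values = [time_response(verhulst_fit, k) for k in range(21)]
        assert np.all(np.diff(values) < 0)

    @pytest.mark.parametrize("horizon", [0, -3])
    def test_nonpositive_horizon_rejected(self, verhulst_fit, horizon):
        with pytest.raises(gs.ValidationError):
            forecast(verhulst_fit, horizon)

    def test_classic_forecast_returns_differences(self):
        spec = gs.LogisticSpec(a=0.12, mu=6.9e-7, x0=109381, n=10)
        x1 = gs.generate_logistic(spec)
        classic = fit(x1, orientation="classic")
        future = forecast(classic, 3)
        assert len(future) == 3 and future.first_year == x1.last_year + 1
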