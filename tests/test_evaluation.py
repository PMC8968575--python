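"""Fit diagnostics, model comparison and the assay-truncation protocol."""

import numpy as np
import pytest

from adkin import (
    FirstOrderParams,
    FitConfig,
    TimeSeries,
    TruncationReport,
    compare_models,
    fit_first_order,
    fit_model,
    prediction_error_at_cutoff,
    relative_error_series,
    simulate_measurements,
    time_reduction_at_threshold,
    truncation_study,
)
from adkin.synthetic import NoiseModel, make_recovery_fixture
from conftest import PRINTED_SETS


@pytest.fixture(scope="module")
def untreated_series():
    p = PRINTED_SETS["untreated"]
    return make_recovery_fixture(p, 5.0 / 0.076, 61)[0]


class TestRelativeError:
    def test_perfect_fit_gives_zeros(self, untreated_series):
        rep = relative_error_series(untreated_series, untreated_series.values)
        assert rep.max_abs == 0.0
        assert rep.n_skipped == 1  # the t=0 zero observation

    def test_proportional_bias_is_constant(self, untreated_series):
        with pytest.warns(UserWarning):
            rep = relative_error_series(untreated_series, 1.05 * untreated_series.values)
        np.testing.assert_allclose(rep.errors, 0.05, rtol=1e-12)

    def test_self_fit_error_is_negligible(self, untreated_series):
        fit = fit_model("proposed", untreated_series)
        rep = relative_error_series(untreated_series, fit.fitted_values(untreated_series))
        assert rep.max_abs < 1e-6


class TestPredictionError:
    def test_zero_on_noiseless_self_generated_data(self, untreated_series):
        horizon = untreated_series.duration
        for cutoff in (0.35 * horizon, 0.6 * horizon):
            err = prediction_error_at_cutoff(untreated_series, "proposed", cutoff)
            assert err < 1e-6

    def test_degenerate_cutoff_equals_full_fit_residual(self, untreated_series):
        err = prediction_error_at_cutoff(
            untreated_series, "first-order", untreated_series.duration
        )
        fit = fit_model("first-order", untreated_series)
        pred = fit.fitted_values(untreated_series)[-1]
        y = untreated_series.values[-1]
        assert err == pytest.approx(abs(pred - y) / y, rel=1e-9)

    def test_infeasible_cutoff_names_minimum(self, untreated_series):
        with pytest.raises(ValueError, match="earliest feasible cutoff"):
            prediction_error_at_cutoff(untreated_series, "proposed", 0.1)

    def test_asymptote_endpoint_uses_ultimate_potential(self, untreated_series):
        err = prediction_error_at_cutoff(
            untreated_series, "proposed", 0.6 * untreated_series.duration,
            endpoint="asymptote",
        )
        # noiseless self-fit recovers S_max, whereas the curve at the final
        # time is still below it
        expected = abs(PRINTED_SETS["untreated"].s_a0 - untreated_series.values[-1])
        assert err == pytest.approx(expected / untreated_series.values[-1], rel=1e-4)


class TestTruncationStudy:
    def test_noiseless_errors_all_zero_and_reduction_large(self, untreated_series):
        cutoffs = untreated_series.times[[12, 24, 36, 48, 60]]
        reports = truncation_study(untreated_series, ["proposed"], cutoffs)
        rep = reports["proposed"]
        assert np.nanmax(rep.prediction_errors) < 1e-6
        expected = 100.0 * (1.0 - cutoffs[0] / untreated_series.duration)
        assert rep.time_reduction == pytest.approx(expected)

    def test_infeasible_cutoffs_marked_absent(self, untreated_series):
        reports = truncation_study(
            untreated_series, ["proposed"], [0.5, untreated_series.duration]
        )
        errs = reports["proposed"].prediction_errors
        assert np.isnan(errs[0]) and np.isfinite(errs[1])

    def test_deterministic_for_fixed_seed(self):
        p = PRINTED_SETS["untreated"]
        series = simulate_measurements(
            "proposed", p, np.linspace(0.0, 5.0 / 0.076, 41),
            NoiseModel("additive-gaussian", 0.02, seed=9),
        )
        cutoffs = series.times[[20, 30, 40]]
        r1 = truncation_study(series, ["proposed"], cutoffs, FitConfig(seed=1))
        r2 = truncation_study(series, ["proposed"], cutoffs, FitConfig(seed=1))
        np.testing.assert_array_equal(
            r1["proposed"].prediction_errors, r2["proposed"].prediction_errors
        )


class TestTimeReduction:
    def _report(self, cutoffs, errors, threshold=0.05):
        return TruncationReport(
            "proposed", np.array(cutoffs, float), np.array(errors, float), threshold, 0.0
        )

    def test_all_below_threshold_counts_from_earliest_cutoff(self):
        rep = self._report([40.0, 60.0, 80.0], [0.01, 0.02, 0.001])
        assert time_reduction_at_threshold(rep, 100.0) == pytest.approx(60.0)

    def test_no_cutoff_below_threshold_gives_zero(self):
        rep = self._report([40.0, 60.0, 80.0], [0.3, 0.2, 0.1])
        assert time_reduction_at_threshold(rep, 100.0) == 0.0

    def test_crossing_must_be_sustained(self):
        # a transient dip below threshold does not justify stopping the assay
        rep = self._report([20.0, 40.0, 60.0, 80.0], [0.01, 0.2, 0.03, 0.01])
        assert time_reduction_at_threshold(rep, 100.0) == pytest.approx(40.0)

    def test_anti_monotone_in_threshold(self):
        cutoffs = [20.0, 40.0, 60.0, 80.0]
        errors = [0.08, 0.04, 0.02, 0.01]
        reductions = [
            time_reduction_at_threshold(self._report(cutoffs, errors, th), 100.0)
            for th in (0.10, 0.05, 0.03, 0.015, 0.005)
        ]
        assert all(a >= b for a, b in zip(reductions, reductions[1:]))


class TestCompareModels:
    def test_dual_pool_data_ranks_dual_pool_first(self, untreated_series):
        table = compare_models(
            untreated_series, ["proposed", "first-order", "three-phase", "gompertz"]
        )
        assert table.iloc[0]["model"] == "proposed"
        assert table.iloc[0]["r2"] == pytest.approx(1.0, abs=1e-9)

    def test_flags_impossible_ultimate_potential(self, untreated_series):
        # simpler models saturate below the last observation on this curve
        table = compare_models(untreated_series, ["first-order", "gompertz"])
        assert all("smax_below_last" in f for f in table["flags"])

    def test_exactly_nested_model_matches_first_order_optimum(self):
        data = simulate_measurements(
            "first-order", FirstOrderParams(100.0, 0.2), np.linspace(0, 30, 31)
        )
        fo = fit_first_order(data)
        # dual-pool single-phase contains first-order exactly (equal pool rates)
        nested = fit_model(
            "dual-pool-single", data,
            init=[fo.params.s, 0.5, fo.params.k_1a, fo.params.k_1a],
        )
        assert nested.objective <= fo.objective + 1e-9
        assert nested.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_failures_recorded_not_fatal(self):
        t = np.linspace(0, 5, 6)
        series = TimeSeries(t, np.linspace(0, 10, 6))
        table = compare_models(series, ["proposed", "first-order"])  # proposed needs >6 pts
        row = table[table.model == "proposed"].iloc[0]
        assert "error" in row["flags"]
        assert np.isfinite(table[table.model == "first-order"].iloc[0]["r2"])


class TestPredictionErrorSimulation:
    def test_errors_shrink_with_later_cutoffs_under_noise(self):
        """Median prediction error decreases as more of the assay is used."""
        p = PRINTED_SETS["untreated"]
        horizon = 5.0 / 0.076
        schedule = np.linspace(0.0, horizon, 41)
        frac_errors = {0.25: [], 0.5: [], 0.75: []}
        for rep in range(12):
            series = simulate_measurements(
                "proposed", p, schedule,
                NoiseModel("additive-gaussian", 0.02, seed=100 + rep),
            )
            for frac in frac_errors:
                frac_errors[frac].append(
                    prediction_error_at_cutoff(series, "proposed", frac * horizon)
                )
        medians = [np.median(frac_errors[f]) for f in (0.25, 0.5, 0.75)]
        assert medians[0] >= medians[1] >= medians[2]
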