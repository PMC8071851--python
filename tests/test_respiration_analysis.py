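"""Rate/ratio extraction, outlier filter, resampling, growth fits."""

import numpy as np
import pytest

from breathsync import (
    OnsetEvent,
    OnsetKind,
    cycle_metrics,
    design_matrix,
    extract_series,
    fit_growth,
    orthogonal_basis,
    outlier_filter,
    resample,
    sliding_median,
    tidy_table,
)
from tests.conftest import periodic_events


def events_from(times_kinds):
    return [OnsetEvent(t, k) for t, k in times_kinds]


class TestCycleMetrics:
    def test_iots_are_event_differences(self):
        evs = events_from(
            [
                (0, OnsetKind.INHALE), (2, OnsetKind.EXHALE),
                (6, OnsetKind.INHALE), (8, OnsetKind.EXHALE),
                (12, OnsetKind.INHALE),
            ]
        )
        iot_t, iots, _, _ = cycle_metrics(evs)
        assert list(iots) == [2, 4, 2, 4]
        assert list(iot_t) == [2, 6, 8, 12]

    def test_perfect_1_2_cycles_give_ratio_two(self, clean_trial):
        _, _, _, ratios = cycle_metrics(clean_trial)
        assert len(ratios) > 70
        assert np.allclose(ratios, 2.0)

    def test_missing_exhale_drops_that_cycle_ratio(self):
        # I E I I E I: middle cycle lacks its exhale press.
        evs = events_from(
            [
                (0, OnsetKind.INHALE), (2, OnsetKind.EXHALE),
                (6, OnsetKind.INHALE), (12, OnsetKind.INHALE),
                (14, OnsetKind.EXHALE), (18, OnsetKind.INHALE),
            ]
        )
        _, iots, rt, ratios = cycle_metrics(evs)
        assert len(ratios) == 2  # first and last cycles only
        assert list(rt) == [6, 18]
        assert len(iots) == 5  # IOT stream unaffected

    def test_fewer_than_two_events_empty(self):
        for evs in ([], [OnsetEvent(0, OnsetKind.INHALE)]):
            out = cycle_metrics(evs)
            assert all(len(x) == 0 for x in out)


class TestSlidingMedian:
    def test_constant_six_second_cycles_give_ten_bpm(self, clean_trial):
        _, med, rates = sliding_median(clean_trial)
        assert np.allclose(rates, 10.0)

    def test_constant_value_median_everywhere(self):
        evs = [
            OnsetEvent(3.0 * i, OnsetKind.INHALE if i % 2 == 0 else OnsetKind.EXHALE)
            for i in range(12)
        ]
        _, med, _ = sliding_median(evs)
        assert np.allclose(med, 3.0)

    def test_median_robust_to_single_outlier_iot(self):
        # One long gap: windows containing it keep the constant median.
        times = [0, 2, 4, 6, 8, 10, 30, 32, 34, 36, 38, 40]
        evs = [
            OnsetEvent(t, OnsetKind.INHALE if i % 2 == 0 else OnsetKind.EXHALE)
            for i, t in enumerate(times)
        ]
        _, med, _ = sliding_median(evs)
        # 5 IOTs per window, at most 1 outlier -> median stays 2.
        assert np.allclose(med, 2.0)

    def test_window_timestamp_is_median_event_time(self):
        evs = [
            OnsetEvent(float(t), OnsetKind.INHALE if i % 2 == 0 else OnsetKind.EXHALE)
            for i, t in enumerate([0, 1, 2, 3, 4, 5, 6])
        ]
        w_times, _, _ = sliding_median(evs)
        assert w_times[0] == pytest.approx(2.5)  # median of 0..5

    def test_short_stream_empty_output(self):
        evs = [OnsetEvent(float(i), OnsetKind.INHALE) for i in range(5)]
        w, m, r = sliding_median(evs)
        assert len(w) == len(m) == len(r) == 0


class TestOutlierFilter:
    def test_clean_periodic_input_nothing_skipped(self, clean_trial):
        _, iots, _, _ = cycle_metrics(clean_trial)
        kept, skipped = outlier_filter(np.arange(len(iots)), iots)
        assert skipped == 0.0
        assert kept.all()

    def test_spike_beyond_5sd_of_noised_window_discarded(self, rng):
        # Previous window values with known spread, then a 10-SD spike.
        base = np.array([2.0, 2.1, 1.9, 2.05, 1.95])
        sd = base.std(ddof=1)
        spike = base.mean() + 10.0 * sd
        values = np.concatenate([base, [spike], base])
        kept, skipped = outlier_filter(np.arange(len(values)), values)
        assert not kept[5]
        assert kept[np.arange(len(values)) != 5].all()
        assert skipped == pytest.approx(100.0 / len(values))

    def test_within_5sd_kept(self):
        base = np.array([2.0, 2.1, 1.9, 2.05, 1.95])
        ok = base.mean() + 4.0 * base.std(ddof=1)
        values = np.concatenate([base, [ok]])
        kept, _ = outlier_filter(np.arange(len(values)), values)
        assert kept.all()

    def test_zero_sd_epsilon_guard(self):
        values = np.array([2.0] * 5 + [2.001])
        kept, _ = outlier_filter(np.arange(6), values)
        assert not kept[5]

    def test_discarded_values_excluded_from_later_windows(self):
        # The spike must not contaminate the reference window after it.
        base = [2.0, 2.1, 1.9, 2.05, 1.95]
        values = np.array(base + [50.0] + base * 2)
        kept, _ = outlier_filter(np.arange(len(values)), values)
        assert not kept[5]
        assert kept[6:].all()

    def test_double_press_injection_raises_discard_count(self):
        """k injected double-presses discard at least k-1 IOT values.

        Uses a 1:1-ratio trial: against an alternating short/long IOT
        background the window SD is of the order of the half-cycle
        asymmetry itself and the 5-SD rule cannot flag double presses;
        against a near-constant IOT stream it does.
        """
        trial = periodic_events(period=6.0, ratio=1.0)
        k = 4
        events = sorted(
            trial
            + [
                OnsetEvent(trial[i].time + 0.05, trial[i].kind)
                for i in (10, 20, 30, 40)
            ],
            key=lambda e: e.time,
        )
        _, iots, _, _ = cycle_metrics(events)
        kept, _ = outlier_filter(np.arange(len(iots)), iots)
        assert (~kept).sum() >= k - 1


class TestResample:
    def test_480s_trial_gives_48_samples(self):
        grid, vals = resample(np.array([0.0, 480.0]), np.array([1.0, 2.0]))
        assert len(grid) == 48
        assert grid[0] == 0.0 and grid[-1] == 470.0

    def test_constant_input_constant_output(self):
        grid, vals = resample(np.array([10.0, 400.0]), np.array([5.0, 5.0]))
        assert np.all(vals == 5.0)

    def test_linear_ramp_exact(self):
        t = np.linspace(0, 480, 20)
        v = 3.0 + 0.01 * t
        grid, vals = resample(t, v)
        np.testing.assert_allclose(vals, 3.0 + 0.01 * grid, rtol=1e-12)

    def test_edges_hold_nearest_value(self):
        grid, vals = resample(np.array([100.0, 200.0]), np.array([1.0, 2.0]))
        assert vals[0] == 1.0 and vals[-1] == 2.0

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            resample(np.array([1.0]), np.array([1.0]))


class TestOrthogonalBasis:
    def test_gram_identity(self):
        B = orthogonal_basis(48, 4)
        np.testing.assert_allclose(B.T @ B, np.eye(5), atol=1e-10)

    def test_column_zero_constant(self):
        B = orthogonal_basis(48, 4)
        assert np.allclose(B[:, 0], B[0, 0]) and B[0, 0] > 0

    def test_column_one_increasing_zero_mean(self):
        B = orthogonal_basis(48, 4)
        assert np.all(np.diff(B[:, 1]) > 0)
        assert abs(B[:, 1].sum()) < 1e-10

    @pytest.mark.parametrize("n,degree", [(10, 4), (48, 4), (100, 3)])
    def test_shapes(self, n, degree):
        assert orthogonal_basis(n, degree).shape == (n, degree + 1)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            orthogonal_basis(4, 4)


class TestFitGrowth:
    def test_constant_series_intercept_log_c(self):
        fit = fit_growth(np.full(48, 7.5))
        assert fit.coefficients[0] == pytest.approx(np.log(7.5), abs=1e-10)
        assert np.allclose(fit.coefficients[1:], 0.0, atol=1e-10)

    def test_exact_recovery_of_synthesized_coefficients(self):
        B = orthogonal_basis(48, 4)
        X = design_matrix(B)
        beta = np.array([2.0, -0.46, 0.2, -0.05, 0.096])
        series = np.exp(X @ beta)
        fit = fit_growth(series, basis=B)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)

    def test_non_positive_value_error_names_index(self):
        vals = np.full(48, 2.0)
        vals[13] = 0.0
        with pytest.raises(ValueError, match="13"):
            fit_growth(vals)

    def test_monte_carlo_standard_errors_match_analytic(self, rng):
        """SEs of orthonormal-basis OLS approach sigma per coefficient."""
        B = orthogonal_basis(48, 4)
        X = design_matrix(B)
        beta = np.array([2.0, -0.3, 0.1, 0.0, 0.05])
        sigma = 0.05
        ses = []
        for _ in range(200):
            y = np.exp(X @ beta + sigma * rng.standard_normal(48))
            ses.append(fit_growth(y, basis=B).standard_errors)
        mean_se = np.mean(ses, axis=0)
        analytic = sigma * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(mean_se, analytic, rtol=0.2)

    def test_per_condition_fits(self):
        B = orthogonal_basis(48, 4)
        X = design_matrix(B)
        series = np.vstack(
            [
                np.exp(X @ np.array([2.0, -0.4, 0.0, 0.0, 0.0])),
                np.exp(X @ np.array([2.0, 0.3, 0.1, 0.0, 0.0])),
            ]
        )
        fit = fit_growth(series, basis=B, conditions=["nature", "noise"])
        assert fit.conditions == ["nature", "noise"]
        assert fit.coefficients[0, 1] == pytest.approx(-0.4, abs=1e-8)
        assert fit.coefficients[1, 1] == pytest.approx(0.3, abs=1e-8)


class TestPipeline:
    def test_clean_trial_rate_series(self, clean_trial):
        s = extract_series(clean_trial, "rate")
        assert len(s.grid_values) == 48
        assert s.skipped_fraction == 0.0
        np.testing.assert_allclose(s.grid_values, 10.0, rtol=1e-9)

    def test_clean_trial_ratio_series(self, clean_trial):
        s = extract_series(clean_trial, "ratio")
        assert len(s.grid_values) == 48
        np.testing.assert_allclose(s.grid_values, 2.0, rtol=1e-9)

    def test_pipeline_deterministic(self, clean_trial):
        a = extract_series(clean_trial, "rate")
        b = extract_series(clean_trial, "rate")
        assert np.array_equal(a.grid_values, b.grid_values)
        fa = fit_growth(a.grid_values)
        fb = fit_growth(b.grid_values)
        assert np.array_equal(fa.coefficients, fb.coefficients)

    def test_tidy_table_shape_and_columns(self, clean_trial):
        s = extract_series(clean_trial, "rate")
        df = tidy_table([s, s], trial_ids=["a", "b"], conditions=["No", "Na"])
        assert len(df) == 96
        assert set(df.columns) >= {
            "trial", "condition", "grid_time", "value", "log_value",
        }
        np.testing.assert_allclose(df["log_value"], np.log(df["value"]))
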