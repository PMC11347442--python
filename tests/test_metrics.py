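import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import loadlab as ll
import oracles
from conftest import make_random_series
from loadlab.metrics import (
    ALL_MISSING,
    BURN_IN,
    ZERO_PREVIOUS_WEEK,
    ZERO_VARIABILITY,
    metric_series,
)

CONST = np.full(60, 100.0)


class TestAcuteLoad:
    def test_constant_week_sums_to_seven_times_daily(self):
        assert ll.acute_load(CONST, 30, 7) == 700.0

    def test_all_zero_week_sums_to_zero(self):
        assert ll.acute_load(np.zeros(10), 9, 7) == 0.0

    def test_burn_in_days_are_nan(self):
        assert np.isnan(ll.acute_load(CONST, 5, 7))

    def test_matches_brute_force_sum_everywhere(self, rng):
        w = make_random_series(rng, 60)
        for day in range(60):
            expected = oracles.acute_load(w, day)
            got = ll.acute_load(w, day)
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == expected


class TestRatioExamples:
    """Hand-computable window arithmetic for each ratio metric."""

    def test_coupled_acwr_from_stated_block_sums(self):
        # acute week 600, four-week block sums (600, 500, 450, 450)
        w = np.concatenate([
            np.full(7, 450 / 7), np.full(7, 450 / 7),
            np.full(7, 500 / 7), np.full(7, 600 / 7),
        ])
        assert ll.coupled_acwr(w, 27) == pytest.approx(600 / 500, abs=1e-12)

    def test_uncoupled_acwr_from_stated_block_sums(self):
        # acute 700, three prior weeks 350 each
        w = np.concatenate([np.full(21, 50.0), np.full(7, 100.0)])
        assert ll.uncoupled_acwr(w, 27) == pytest.approx(2.0, abs=1e-12)

    def test_uncoupled_exceeds_coupled_when_final_week_doubles(self, rng):
        w = make_random_series(rng, 35, zero_fraction=0.0) + 50.0
        w[-7:] *= 2.0
        day = 34
        assert ll.uncoupled_acwr(w, day) > ll.coupled_acwr(w, day)

    def test_weekly_change_ratio_direct(self):
        w = np.concatenate([np.full(7, 400 / 7), np.full(7, 500 / 7)])
        assert ll.weekly_change_ratio(w, 13) == pytest.approx(1.25, abs=1e-12)

    def test_weekly_change_ratio_identical_weeks_is_one(self):
        assert ll.weekly_change_ratio(CONST, 20) == pytest.approx(1.0)

    def test_weekly_change_zero_previous_week_is_flagged(self):
        w = np.concatenate([np.zeros(7), np.full(7, 100.0)])
        vals, reasons = metric_series(w, "diff")
        assert np.isnan(vals[13]) and reasons[13] == ZERO_PREVIOUS_WEEK


class TestMonotony:
    def test_flat_week_is_degenerate(self):
        vals, reasons = metric_series(CONST, "monotony")
        assert np.isnan(vals[30]) and reasons[30] == ZERO_VARIABILITY

    def test_scale_invariance(self, rng):
        w = make_random_series(rng, 30, zero_fraction=0.0)
        assert ll.monotony(3.7 * w, 20) == pytest.approx(ll.monotony(w, 20), rel=1e-12)

    def test_matches_mean_over_sd_oracle(self):
        w = np.array([100.0] * 6 + [200.0])
        assert ll.monotony(w, 6) == pytest.approx(oracles.monotony(w, 6), abs=1e-12)


class TestSdDelta:
    def test_zero_when_acute_week_at_historical_mean(self):
        assert ll.sd_delta(CONST, 40) == 0.0
        cfg = ll.MetricConfig(sddelta_denominator="variance")
        assert ll.sd_delta(CONST, 40, cfg) == 0.0

    def test_one_sd_above_mean_scores_one(self):
        # prior weekly block sums 300, 400, 500; acute chosen so that the
        # acute week sits exactly one SD above the four-block mean
        blocks = [300.0, 400.0, 500.0]

        def unit_score_gap(a):
            arr = blocks + [a]
            return (a - np.mean(arr)) / np.std(arr, ddof=1) - 1.0

        from scipy.optimize import brentq
        a = brentq(unit_score_gap, 400.0, 5000.0)
        w = np.concatenate([np.full(7, b / 7) for b in blocks] + [np.full(7, a / 7)])
        assert ll.sd_delta(w, 27) == pytest.approx(1.0, abs=1e-9)

    def test_variance_mode_is_sd_mode_over_block_sd(self, rng):
        w = make_random_series(rng, 40, zero_fraction=0.0)
        day = 35
        sd_mode = ll.sd_delta(w, day)
        var_mode = ll.sd_delta(w, day, ll.MetricConfig(sddelta_denominator="variance"))
        blocks = [oracles.week_sum(w, day, k) for k in range(4)]
        import statistics
        assert var_mode == pytest.approx(sd_mode / statistics.stdev(blocks), rel=1e-9)


class TestEwma:
    def test_decay_time_five_gives_lambda_one_third(self):
        assert ll.MetricConfig(ewma_N=5).ewma_lambda == pytest.approx(1 / 3)

    def test_constant_load_is_a_fixed_point(self):
        e = ll.ewma_series(CONST)
        np.testing.assert_allclose(e, 100.0, atol=1e-12)

    def test_recursion_equals_closed_form_weighted_sum(self, rng):
        w = make_random_series(rng, 50)
        e = ll.ewma_series(w)
        for t in (0, 1, 7, 25, 49):
            assert e[t] == pytest.approx(oracles.ewma_closed_form(w, t), abs=1e-9)

    def test_literal_form_is_standard_over_lambda(self, rng):
        w = make_random_series(rng, 60)
        std = ll.ewma_series(w, ll.MetricConfig(ewma_form="standard"))
        lit = ll.ewma_series(w, ll.MetricConfig(ewma_form="literal"))
        np.testing.assert_allclose(lit, std / (1 / 3), rtol=1e-12)

    def test_both_forms_give_identical_acwr(self, rng):
        w = make_random_series(rng, 90)
        for day in range(27, 90):
            a = ll.ewma_acwr(w, day, ll.MetricConfig(ewma_form="standard"))
            b = ll.ewma_acwr(w, day, ll.MetricConfig(ewma_form="literal"))
            assert a == pytest.approx(b, abs=1e-9)


class TestRedi:
    def test_single_present_day_returns_its_workload(self):
        w = np.array([0.0, 0.0, 0.0, 0.0, 300.0])
        r = ll.redi_series(w)
        assert r[4] == pytest.approx(300.0)

    def test_two_day_window_weighted_mean(self):
        w0, w1 = 500.0, 300.0
        r = ll.redi_series(np.array([w1, w0]), config=ll.MetricConfig(redi_window_days=2))
        expected = (w0 + math.exp(-1) * w1) / (1 + math.exp(-1))
        assert r[1] == pytest.approx(expected, abs=1e-12)

    def test_missing_days_are_skipped_not_averaged_in(self, rng):
        w = make_random_series(rng, 40, zero_fraction=0.3)
        r = ll.redi_series(w)
        for t in range(40):
            expected = oracles.redi_value(list(w), t)
            if expected is None:
                assert np.isnan(r[t])
            else:
                assert r[t] == pytest.approx(expected, abs=1e-12)

    def test_all_missing_acute_week_is_flagged(self):
        # zeros must span the acute week plus the REDI look-back so every
        # daily REDI value inside the acute week is undefined
        w = np.concatenate([np.full(38, 200.0), np.zeros(12)])
        vals, reasons = metric_series(w, "redi_acwr")
        assert np.isnan(vals[49]) and reasons[49] == ALL_MISSING

    def test_explicit_rest_mask_overrides_zero_detection(self):
        w = np.array([100.0, 0.0, 100.0])
        mask = np.array([False, False, False])  # the 0 is a true zero-load day
        r = ll.redi_series(w, rest_mask=mask, config=ll.MetricConfig(redi_window_days=3))
        a = [math.exp(0), math.exp(-1), math.exp(-2)]
        assert r[2] == pytest.approx((a[0] * 100 + a[1] * 0 + a[2] * 100) / sum(a))


@pytest.mark.parametrize("metric", ll.METRIC_NAMES)
def test_metric_series_matches_naive_oracle(metric, rng):
    """Random-series equivalence of the engine and an independent loop oracle."""
    for n in (60, 123, 200):
        w = make_random_series(rng, n)
        vals, reasons = metric_series(w, metric)
        oracle = oracles.METRIC_ORACLES[metric]
        for day in range(n):
            expected = oracle(list(w), day)
            if expected is None:
                assert np.isnan(vals[day]) and reasons[day] is not None
            else:
                assert vals[day] == pytest.approx(expected, abs=1e-9)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**32 - 1), st.integers(40, 80))
def test_ratio_metrics_nonnegative_for_nonnegative_load(seed, n):
    w = make_random_series(np.random.default_rng(seed), n)
    for metric in ("acwr_coupled", "acwr_uncoupled", "diff", "monotony",
                   "ewma_acwr", "redi_acwr"):
        vals, _ = metric_series(w, metric)
        assert np.all(vals[~np.isnan(vals)] >= 0.0)


def test_shift_equivariance(rng):
    """Prepending k days shifts every metric series without changing values."""
    w = make_random_series(rng, 80, zero_fraction=0.0) + 10.0
    prefix = make_random_series(rng, 9, zero_fraction=0.0) + 10.0
    shifted = np.concatenate([prefix, w])
    for metric in ll.METRIC_NAMES:
        base, _ = metric_series(w, metric)
        moved, _ = metric_series(shifted, metric)
        # compare on days with full burn-in in the unshifted series; EWMA-family
        # metrics carry initialization memory, so allow it to wash out first
        start = 55
        np.testing.assert_allclose(moved[start + 9:], base[start:], rtol=1e-6)


class TestPanel:
    def test_default_cohort_panel_shape(self, default_panel, default_cohort):
        assert len(default_panel.values) == 8 * 211
        assert all(m in default_panel.values.columns for m in ll.METRIC_NAMES)

    def test_burn_in_invalidates_first_27_days_of_28_day_metrics(self, default_panel):
        first = default_panel.values[default_panel.values["day_index"] < 27]
        for metric in ("acwr_coupled", "acwr_uncoupled", "sd_delta",
                       "ewma_acwr", "redi_acwr"):
            assert first[metric].isna().all()
            reasons = default_panel.reasons.loc[first.index, metric]
            assert (reasons == BURN_IN).all()

    def test_athlete_order_does_not_change_series(self, default_cohort):
        frame = default_cohort.frame
        reordered = frame.sort_values(
            ["athlete_id", "day_index"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
        panel_a = ll.compute_all_metrics(default_cohort)
        panel_b = ll.compute_all_metrics(ll.TrainingLog.from_frame(reordered))
        a = panel_a.values.set_index(["athlete_id", "day_index"]).sort_index()
        b = panel_b.values.set_index(["athlete_id", "day_index"]).sort_index()
        np.testing.assert_allclose(
            a[list(ll.METRIC_NAMES)].to_numpy(),
            b[list(ll.METRIC_NAMES)].to_numpy(),
            equal_nan=True,
        )

    def test_long_writer_has_validity_bookkeeping(self, default_panel, tmp_path):
        import pandas as pd
        path = tmp_path / "panel.csv"
        default_panel.write(path)
        back = pd.read_csv(path)
        assert set(back.columns) == {
            "athlete_id", "day_index", "metric", "value", "valid", "invalid_reason"
        }
        assert len(back) == 7 * 8 * 211
        assert (~back["valid"]).sum() == back["invalid_reason"].notna().sum()
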