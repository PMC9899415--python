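"""Daily series engine: selection, QC, aggregation, gapfill, smooth, slope."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizopheno import tube_timeseries as ts
from rhizopheno.tube_timeseries import SeriesConfig, SeriesError

from conftest import cycle_records, daily_frame


class TestSelectPositions:
    def _full_cycle(self, n_long=14, n_rot=8):
        rows = []
        for li in range(n_long):
            for ri in range(n_rot):
                rows.append({"instrument": "T0",
                             "cycle_time": pd.Timestamp("2021-03-01 06:00"),
                             "long_idx": li, "rot_idx": ri, "n_rot": n_rot,
                             "value": 1.0})
        return pd.DataFrame(rows)

    def test_horizontal_keeps_three_eighths_of_112(self):
        recs = self._full_cycle()
        assert len(recs) == 112
        kept = ts.select_positions(recs, "horizontal")
        assert len(kept) == 42
        assert set(kept["rot_idx"]) == {7, 0, 1}

    def test_angled_keeps_half_of_112(self):
        kept = ts.select_positions(self._full_cycle(), "angled")
        assert len(kept) == 56
        # side positions survive; top (0) and bottom (4) centred pairs do not
        assert set(kept["rot_idx"]) == {1, 2, 5, 6}

    def test_empty_input(self):
        empty = self._full_cycle().iloc[:0]
        assert ts.select_positions(empty, "horizontal").empty

    def test_unknown_mode_rejected(self):
        with pytest.raises(SeriesError):
            ts.select_positions(self._full_cycle(), "vertical")
        with pytest.raises(SeriesError):
            SeriesConfig(installation="sideways")

    @pytest.mark.parametrize("n_rot,mode,expected_frac", [
        (8, "horizontal", 3 / 8),
        (8, "angled", 4 / 8),
        (12, "angled", 6 / 12),
    ])
    def test_keep_fraction_generalizes(self, n_rot, mode, expected_frac):
        keep = ts.rotational_keep_set(mode, n_rot)
        assert len(keep) / n_rot == expected_frac


class TestQcIllumination:
    def test_below_threshold_fails(self):
        recs = cycle_records([1.0, 2.0, 3.0])
        recs["mean_brightness"] = [50.0, 5.0, 60.0]
        out = ts.qc_illumination(recs, threshold=20.0)
        assert list(out["qc_pass"]) == [True, False, True]

    def test_failed_day_becomes_a_gap(self):
        recs = cycle_records([1.0, 2.0, 3.0])
        recs["mean_brightness"] = [50.0, 5.0, 60.0]
        daily = ts.daily_aggregate(ts.qc_illumination(recs, 20.0), "value")
        assert len(daily) == 2  # the dark day is simply absent

    def test_zero_threshold_and_missing_brightness_pass(self):
        recs = cycle_records([1.0, 2.0])
        assert ts.qc_illumination(recs, threshold=0.0)["qc_pass"].all()
        assert ts.qc_illumination(recs, threshold=None)["qc_pass"].all()


class TestDailyAggregate:
    def test_mean_and_count(self):
        recs = cycle_records([[1.0, 2.0, 3.0]])
        daily = ts.daily_aggregate(recs, "value")
        assert daily["value"].iloc[0] == 2.0
        assert daily["n_images"].iloc[0] == 3

    def test_subdaily_cycles_pool_images_not_cycle_means(self):
        # day with cycles {1} and {2, 2, 2}: pooled mean 7/4, not 1.5
        recs = cycle_records([[1.0, 2.0, 2.0, 2.0]])
        assert ts.daily_aggregate(recs, "value")["value"].iloc[0] == pytest.approx(1.75)

    def test_empty_and_qc_filtered(self):
        assert ts.daily_aggregate(cycle_records([]), "value").empty
        recs = cycle_records([1.0])
        recs["qc_pass"] = False
        assert ts.daily_aggregate(recs, "value").empty


class TestGapfill:
    def test_midpoint_fill(self):
        s = daily_frame([2.0, 4.0]).iloc[[0, 1]]
        s.index = pd.DatetimeIndex(["2021-03-01", "2021-03-03"], name="date")
        out = ts.gapfill_linear(s)
        assert out.loc["2021-03-02", "value"] == 3.0
        assert bool(out.loc["2021-03-02", "gapfilled"])
        assert out.loc["2021-03-02", "n_images"] == 0

    def test_three_day_gap_linear(self):
        s = daily_frame([0.0, 8.0])
        s.index = pd.DatetimeIndex(["2021-03-01", "2021-03-05"], name="date")
        out = ts.gapfill_linear(s)
        assert list(out["value"]) == [0.0, 2.0, 4.0, 6.0, 8.0]

    def test_no_gaps_is_identity_on_observations(self):
        s = daily_frame([1.0, 2.0, 3.0])
        out = ts.gapfill_linear(s)
        pd.testing.assert_frame_equal(out, s)

    def test_observed_values_never_altered(self):
        s = daily_frame([5.0, 1.0, 4.0])
        s = s.iloc[[0, 2]]  # drop the middle day
        out = ts.gapfill_linear(s)
        assert out.loc[s.index, "value"].tolist() == [5.0, 4.0]
        assert not out.loc[s.index, "gapfilled"].any()

    def test_refuses_single_point(self):
        with pytest.raises(SeriesError):
            ts.gapfill_linear(daily_frame([1.0]))


class TestRollingSmooth:
    def test_constant_series_unchanged(self):
        s = daily_frame([3.0] * 10)
        assert ts.rolling_smooth(s, 3)["value"].tolist() == [3.0] * 10

    def test_linear_interior_preserved(self):
        s = daily_frame(2.0 * np.arange(10))
        out = ts.rolling_smooth(s, 3)
        np.testing.assert_allclose(out["value"].iloc[1:-1], s["value"].iloc[1:-1])

    def test_impulse_spreads_over_window(self):
        out = ts.rolling_smooth(daily_frame([0, 0, 3, 0, 0]), 3)
        np.testing.assert_allclose(out["value"], [0, 1, 1, 1, 0])

    def test_bounded_by_input_range(self):
        rng = np.random.default_rng(7)
        s = daily_frame(rng.uniform(0, 10, 30))
        out = ts.rolling_smooth(s, 3)
        assert out["value"].min() >= s["value"].min() - 1e-12
        assert out["value"].max() <= s["value"].max() + 1e-12


class TestGrowthRate:
    def test_exact_linear_slope_everywhere(self):
        s = daily_frame(2.0 * np.arange(15))
        slopes = ts.growth_rate(s, 5)
        np.testing.assert_allclose(slopes, 2.0, atol=1e-12)

    def test_constant_series_zero_slope(self):
        slopes = ts.growth_rate(daily_frame([4.0] * 10), 5)
        np.testing.assert_allclose(slopes, 0.0, atol=1e-12)

    @pytest.mark.parametrize("window", [4, 5, 6, 7])
    def test_window_sizes_agree_on_linear(self, window):
        s = daily_frame(1.5 * np.arange(20))
        np.testing.assert_allclose(ts.growth_rate(s, window), 1.5, atol=1e-12)

    def test_slope_respects_calendar_gaps(self):
        # y = 3*day with one day missing: slopes still exactly 3
        s = daily_frame(3.0 * np.arange(10)).iloc[[0, 1, 2, 4, 5, 6, 7, 8, 9]]
        np.testing.assert_allclose(ts.growth_rate(s, 5), 3.0, atol=1e-12)


class TestNormalize01:
    def test_scales_to_unit_range(self):
        out = ts.normalize01(daily_frame([2.0, 4.0, 6.0]))
        assert out["value"].tolist() == [0.0, 0.5, 1.0]

    def test_idempotent_on_unit_series(self):
        s = daily_frame([0.0, 0.25, 1.0])
        out = ts.normalize01(ts.normalize01(s))
        np.testing.assert_allclose(out["value"], s["value"])

    def test_constant_series_rejected(self):
        with pytest.raises(SeriesError):
            ts.normalize01(daily_frame([5.0, 5.0]))

    def test_slope_consistency_with_normalization(self):
        rng = np.random.default_rng(3)
        s = daily_frame(np.cumsum(rng.uniform(0, 1, 25)))
        span = s["value"].max() - s["value"].min()
        raw = ts.growth_rate(s, 5)
        norm = ts.growth_rate(ts.normalize01(s), 5)
        np.testing.assert_allclose(norm, raw / span, atol=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0.0, 100.0), min_size=3, max_size=40))
def test_smoothing_stays_within_bounds(values):
    """Centred moving means can never escape the input's range."""
    s = daily_frame(values)
    out = ts.rolling_smooth(s, 3)
    assert out["value"].min() >= min(values) - 1e-9
    assert out["value"].max() <= max(values) + 1e-9


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.sets(st.integers(0, 29), min_size=2, max_size=29))
def test_gapfill_preserves_observations_and_fills_interior(observed_days):
    """Every interior day becomes present; observed values stay bit-identical."""
    days = sorted(observed_days)
    idx = pd.DatetimeIndex([pd.Timestamp("2021-03-01") + pd.Timedelta(days=d)
                            for d in days], name="date")
    s = pd.DataFrame({"value": np.sin(np.array(days, float)),
                      "n_images": 1, "gapfilled": False, "smoothed": False},
                     index=idx)
    out = ts.gapfill_linear(s)
    assert len(out) == days[-1] - days[0] + 1
    assert (out.loc[idx, "value"] == s["value"]).all()
    assert not out.loc[idx, "gapfilled"].any()
    assert out["gapfilled"].sum() == len(out) - len(s)
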