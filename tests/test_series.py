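"""Gap imputation, scaling, windowing and prediction clipping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glybench.errors import (
    ExtrapolationError,
    InvalidPredictionError,
    InvalidStatsError,
    UnfillableSeriesError,
)
from glybench.series import (
    BG_SCALE,
    PatientSeries,
    ScalingStats,
    clip_predictions,
    compute_scaling_stats,
    fill_gaps,
    make_windows,
    read_series_csv,
    scale_features,
    write_series_csv,
)

from .conftest import make_series


class TestFillGaps:
    def test_complete_series_unchanged(self):
        s = make_series([120.0] * 10)
        out = fill_gaps(s)
        np.testing.assert_array_equal(out.bg, s.bg)

    def test_constant_values_fill_constant(self):
        bg = np.array([120.0] * 4 + [np.nan] + [120.0] * 4)
        out = fill_gaps(make_series(bg))
        assert out.bg[4] == pytest.approx(120.0)

    def test_cubic_signal_reproduced_exactly(self):
        # t^3 sampled off the glucose scale: a not-a-knot cubic spline
        # through >= 4 points reproduces any cubic polynomial exactly,
        # so the filled value is 4^3 = 64 (verified independently with
        # scipy.interpolate before freezing).
        t = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8], dtype=float)
        bg = t**3
        bg[4] = np.nan
        out = fill_gaps(make_series(bg, scaled=True))
        assert out.bg[4] == pytest.approx(64.0, abs=1e-8)

    def test_filled_values_clipped_to_cgm_range(self):
        # spline overshoot beyond 400 is clipped
        bg = np.array([390, 395, 398, 399, np.nan, 399, 398, 395, 390], dtype=float)
        out = fill_gaps(make_series(bg))
        assert out.bg[4] <= 400.0

    def test_idempotent(self, patient):
        once = fill_gaps(patient)
        twice = fill_gaps(once)
        np.testing.assert_array_equal(once.bg, twice.bg)

    def test_too_few_anchors_raises(self):
        bg = np.array([100.0, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 110.0, np.nan, 100.0])
        with pytest.raises(UnfillableSeriesError):
            fill_gaps(make_series(bg))

    def test_leading_gap_raises(self):
        bg = np.array([np.nan] + [120.0] * 9)
        with pytest.raises(ExtrapolationError):
            fill_gaps(make_series(bg))

    def test_long_gaps_flagged(self):
        bg = np.full(60, 120.0)
        bg[10:24] = np.nan  # 70 min gap
        out = fill_gaps(make_series(bg), long_gap_minutes=60.0)
        assert out.long_gap_flags[10:24].all()
        assert not out.long_gap_flags[:10].any()


class TestScaling:
    def test_bg_times_hundredth(self):
        s = make_series([100.0] * 30, test_tail=5)
        out = scale_features(s, compute_scaling_stats(s))
        assert out.bg[0] == pytest.approx(1.0)

    def test_minmax_midpoint(self):
        ch = np.zeros(30)
        ch[3] = 80.0
        ch[4] = 40.0
        s = make_series([100.0] * 30, ch=ch, test_tail=5)
        out = scale_features(s, compute_scaling_stats(s))
        assert out.ch[4] == pytest.approx(0.5)
        assert out.ch[3] == pytest.approx(1.0)

    def test_constant_channel_maps_to_zero(self):
        s = make_series([100.0] * 30, bol=np.zeros(30), test_tail=5)
        out = scale_features(s, compute_scaling_stats(s))
        assert np.all(out.bol == 0.0)

    def test_invalid_stats_rejected(self):
        s = make_series([100.0] * 30, test_tail=5)
        bad = ScalingStats(minmax={"bas": (1.0, 0.0), "bol": (0.0, 1.0), "ch": (0.0, 1.0)})
        with pytest.raises(InvalidStatsError):
            scale_features(s, bad)

    def test_bg_roundtrip_within_float_rounding(self, clean_patient):
        stats = compute_scaling_stats(clean_patient)
        out = scale_features(clean_patient, stats)
        np.testing.assert_allclose(out.bg / BG_SCALE, clean_patient.bg, rtol=1e-14)

    def test_stats_come_from_training_partition_only(self):
        ch = np.zeros(40)
        ch[35] = 500.0  # extreme value in the test tail
        ch[2] = 10.0
        s = make_series([100.0] * 40, ch=ch, test_tail=8)
        stats = compute_scaling_stats(s)
        assert stats.minmax["ch"][1] == 10.0


class TestWindows:
    def test_minimal_length_single_sample(self):
        s = make_series([100.0] * 31, scaled=True)
        w = make_windows(s, horizons=(30,))
        assert len(w) == 1

    @pytest.mark.parametrize(
        "length,horizons,expected",
        [(100, (30,), 70), (100, (30, 60, 120), 52)],
    )
    def test_sample_counts(self, length, horizons, expected):
        s = make_series(np.linspace(1.0, 2.0, length), scaled=True)
        w = make_windows(s, horizons=horizons)
        assert len(w) == expected
        assert set(w.targets) == set(horizons)

    @given(length=st.integers(min_value=25, max_value=200))
    @settings(max_examples=40, deadline=None)
    def test_count_matches_enumeration_oracle(self, length):
        import warnings as _warnings

        s = make_series(np.linspace(1.0, 2.0, length), scaled=True)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            w = make_windows(s, horizons=(30,))
        # oracle: enumerate window end positions directly
        count = sum(
            1
            for end in range(length)
            if end >= 24 and end + 6 < length
        )
        assert len(w) == max(count, 0)

    def test_too_short_partition_warns_and_is_empty(self):
        s = make_series([100.0] * 20, scaled=True)
        with pytest.warns(UserWarning):
            w = make_windows(s, horizons=(30,))
        assert len(w) == 0

    def test_targets_are_future_bg(self):
        bg = np.arange(100, dtype=float)
        s = make_series(bg, scaled=True)
        w = make_windows(s, horizons=(30,))
        # window ending at step 24 targets step 30
        assert w.targets[30][0] == bg[30]
        np.testing.assert_array_equal(w.inputs[0, :, 0], bg[:25])

    def test_windows_do_not_cross_partition_boundary(self):
        bg = np.concatenate([np.ones(60), 2 * np.ones(40)])
        s = make_series(bg, test_tail=40, scaled=True)
        w_train = make_windows(s, horizons=(30,), partition="train")
        w_test = make_windows(s, horizons=(30,), partition="test")
        assert np.all(w_train.inputs[:, :, 0] == 1.0)
        assert np.all(w_train.targets[30] == 1.0)
        assert np.all(w_test.inputs[:, :, 0] == 2.0)


class TestClip:
    @pytest.mark.parametrize("value,expected", [(120.0, 120.0), (10.0, 40.0), (1000.0, 400.0)])
    def test_bounds(self, value, expected):
        assert clip_predictions(np.array([value]))[0] == expected

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidPredictionError, match="zhu"):
            clip_predictions(np.array([np.nan]), model_id="zhu")


def test_csv_roundtrip(tmp_path, clean_patient):
    csv_path = tmp_path / "cohort.csv"
    split_path = tmp_path / "split.json"
    write_series_csv([clean_patient], csv_path, split_path)
    back = read_series_csv(csv_path, split_path)
    assert len(back) == 1
    np.testing.assert_allclose(back[0].bg, clean_patient.bg)
    np.testing.assert_array_equal(back[0].split, clean_patient.split)
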