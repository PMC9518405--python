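"""Segmentation, resampling, min-max scaling and Fisher-Yates labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgwell import (
    apply_minmax,
    build_segment_dataset,
    fisher_yates_labels,
    fit_minmax,
    generate_record,
    resample_window,
    segment_signal,
)
from ecgwell.errors import DimensionError, InvalidArgumentError, ValidationError
from ecgwell.synthetic_ecg import ECGRecord


def _record(duration_s, fs=500.0):
    n = int(round(fs * duration_s))
    return ECGRecord(samples=np.zeros(n), fs=fs, subject_id="S0", day_index=1, hi=3)


class TestSegmentSignal:
    @pytest.mark.parametrize(
        "duration,window,step,expected",
        [(20, 5, 1, 16), (25, 5, 1, 21), (5, 5, 1, 1), (22.5, 5, 1, 18), (20, 5, 2.5, 7)],
    )
    def test_window_count_formula(self, duration, window, step, expected):
        windows = segment_signal(_record(duration), window_s=window, step_s=step)
        assert len(windows) == expected
        assert len(windows) == int(np.floor((duration - window) / step)) + 1

    def test_windows_cover_expected_spans(self):
        rec = ECGRecord(np.arange(10_000.0), 500.0, "S0", 1, 3)
        windows = segment_signal(rec, 5, 1)
        for k, win in enumerate(windows):
            assert win.start_s == pytest.approx(k * 1.0)
            assert len(win.values) == 2500
            assert win.values[0] == k * 500  # sample index at k*step_s

    def test_short_record_yields_empty_not_error(self):
        assert segment_signal(_record(3.0), 5, 1) == []

    def test_nonpositive_window_rejected(self):
        with pytest.raises(InvalidArgumentError):
            segment_signal(_record(20), window_s=0)


class TestResampleWindow:
    def test_constant_window_stays_constant(self):
        out = resample_window(np.full(2500, 3.7), 500)
        assert len(out) == 500
        np.testing.assert_allclose(out, 3.7, atol=1e-3)

    def test_sine_keeps_its_frequency(self):
        t = np.arange(2500) / 500.0
        out = resample_window(np.sin(2 * np.pi * 5 * t), 500)
        spec = np.abs(np.fft.rfft(out))
        # 500 points over 5 s -> 100 Hz; bin k maps to k/5 Hz
        assert np.argmax(spec) / 5.0 == pytest.approx(5.0)

    def test_identity_when_lengths_match(self):
        x = np.random.default_rng(0).normal(size=500)
        np.testing.assert_array_equal(resample_window(x, 500), x)

    def test_upsampling_rejected(self):
        with pytest.raises(InvalidArgumentError):
            resample_window(np.zeros(100), 500)


class TestMinMax:
    def test_basic_column_scaling(self):
        model = fit_minmax(np.array([[0.0], [5.0], [10.0]]))
        np.testing.assert_allclose(
            apply_minmax(model, np.array([[0.0], [5.0], [10.0]])).ravel(), [0, 0.5, 1]
        )

    def test_constant_column_maps_to_zero(self):
        model = fit_minmax(np.array([[3.0], [3.0], [3.0]]))
        np.testing.assert_array_equal(apply_minmax(model, np.array([[3.0], [3.0]])).ravel(), 0.0)

    def test_extrapolation_beyond_training_range(self):
        model = fit_minmax(np.array([[0.0], [10.0]]))
        assert apply_minmax(model, np.array([[20.0]]))[0, 0] == pytest.approx(2.0)

    def test_feature_count_mismatch_rejected(self):
        model = fit_minmax(np.zeros((3, 4)))
        with pytest.raises(DimensionError):
            apply_minmax(model, np.zeros((2, 5)))

    @given(
        st.lists(
            st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=3),
            min_size=2,
            max_size=20,
        )
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_training_output_in_unit_interval_and_idempotent(self, rows):
        X = np.array(rows)
        model = fit_minmax(X)
        out = apply_minmax(model, X)
        assert np.all(out >= -1e-12) and np.all(out <= 1 + 1e-12)
        # re-fitting on the scaled data and re-applying changes nothing
        out2 = apply_minmax(fit_minmax(out), out)
        np.testing.assert_allclose(out2, out, atol=1e-9)


class TestFisherYatesLabels:
    def test_increasing_series_label_pattern(self):
        """An ascending 3-day HI series labels the top day Better, the rest Worse."""
        values, labels = fisher_yates_labels([3, 4, 5])
        assert labels.tolist() == [1, 1, 0]
        assert values[0] < values[1] < values[2]

    def test_all_identical_series_all_worse(self):
        values, labels = fisher_yates_labels([4, 4, 4, 4])
        np.testing.assert_array_equal(values, 0.0)
        assert labels.tolist() == [1, 1, 1, 1]

    def test_median_rank_maps_to_zero(self):
        values, _ = fisher_yates_labels([3, 4, 5])  # middle rank: G/(I+1) = 1/2
        assert values[1] == pytest.approx(0.0)

    def test_out_of_range_hi_rejected(self):
        with pytest.raises(ValidationError):
            fisher_yates_labels([1, 2, 6])

    @given(st.lists(st.integers(1, 5), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_monotone_in_hi_and_label_marginals(self, his):
        values, labels = fisher_yates_labels(his)
        assert np.all(np.isfinite(values))
        order = np.argsort(his, kind="stable")
        assert np.all(np.diff(values[order]) >= -1e-12)  # monotone in HI
        # label-0 fraction equals fraction of strictly positive scores, exactly
        assert np.sum(labels == 0) == np.sum(values > 0)


class TestBuildSegmentDataset:
    @pytest.fixture
    def cohort(self):
        recs = []
        his = {1: 2, 2: 4, 3: 5, 4: 3, 5: 1}
        for day, hi in his.items():
            rec = generate_record(
                250, 6.0, "better" if hi >= 3 else "worse", seed=day,
                subject_id="S0", day_index=day, hi=hi,
            )
            recs.append(rec)
        return recs

    def test_one_day_forward_pairing(self, cohort):
        ds = build_segment_dataset(cohort, target_len=500, lag_days=1)
        # day 5 has no day-6 label -> only days 1..4 contribute, 2 windows each
        assert ds.n == 8
        _, day_labels = fisher_yates_labels([2, 4, 5, 3, 1])
        for day in (1, 2, 3, 4):
            got = ds.labels[ds.provenance["day_index"] == day]
            assert np.all(got == day_labels[day])  # label of day+1

    def test_lag_zero_uses_same_day(self, cohort):
        ds = build_segment_dataset(cohort, target_len=500, lag_days=0)
        assert ds.n == 10

    def test_class_labels_follow_generator_regime(self, cohort):
        ds = build_segment_dataset(cohort, target_len=500, label_source="class")
        for wc, lab in zip(ds.provenance["wellness_class"], ds.labels):
            assert lab == (0 if wc == "better" else 1)

    def test_csv_round_trip(self, cohort, tmp_path):
        ds = build_segment_dataset(cohort, target_len=500, lag_days=1)
        path = tmp_path / "segments.csv"
        ds.to_csv(path)
        back = ds.from_csv(path)
        np.testing.assert_allclose(back.X, ds.X, atol=1e-9)
        np.testing.assert_array_equal(back.labels, ds.labels)
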