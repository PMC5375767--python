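"""Event matching, the four metrics, threshold calibration and cross-validation."""

import numpy as np
import pytest

from seizurespec import (
    DetectionEvent,
    FoldDataset,
    MatchCounts,
    RunConfig,
    ScoreTrace,
    SeizureAnnotation,
    compute_metrics,
    crossval,
    fp_hour_histogram,
    format_fpr,
    format_pct,
    match_events,
    mean_metrics,
    optimize_threshold,
)
from seizurespec.evaluation import FoldMetrics


def _event(onset, offset, peak=5.0):
    return DetectionEvent(onset_s=onset, offset_s=offset, peak_score=peak)


class TestMatchEvents:
    def test_overlapping_detection_counts_seizure(self):
        ann = SeizureAnnotation(intervals=[(100.0, 200.0)])
        counts = match_events([_event(150.0, 180.0)], ann, duration_h=1.0)
        assert (counts.tp_events, counts.fn_seizures, counts.fp_events) == (1, 0, 0)

    def test_detection_outside_seizure_is_fp_and_fn(self):
        ann = SeizureAnnotation(intervals=[(100.0, 200.0)])
        counts = match_events([_event(300.0, 320.0)], ann, duration_h=1.0)
        assert (counts.tp_events, counts.fn_seizures, counts.fp_events) == (0, 1, 1)

    def test_two_detections_inside_one_seizure(self):
        ann = SeizureAnnotation(intervals=[(100.0, 200.0)])
        counts = match_events(
            [_event(110.0, 120.0), _event(150.0, 160.0)], ann, duration_h=1.0
        )
        assert counts.fn_seizures == 0
        assert counts.fp_events == 0
        assert counts.detected_seizures == 1

    def test_epoch_tiling_for_specificity(self):
        # 100 s recording, seizure 20-30 s, one FP at 50-52 s
        ann = SeizureAnnotation(intervals=[(20.0, 30.0)])
        counts = match_events(
            [_event(50.0, 52.0)], ann, duration_h=100.0 / 3600.0, epoch_s=5.0
        )
        # epochs 4 and 5 ([20,25),[25,30)) are positive; 18 negatives remain
        assert counts.neg_epochs_total == 18
        assert counts.neg_epochs_flagged == 1  # epoch [50, 55)


class TestComputeMetrics:
    def test_perfect_day(self):
        counts = MatchCounts(1, 0, 0, 1, 17280, 0, 24.0)
        m = compute_metrics(counts)
        assert m.sensitivity_pct == 100.0
        assert m.fpr_per_24h == 0.0
        assert m.ppv_pct == 100.0

    def test_fold5_style_arithmetic(self):
        # tp=1, fp=2 over 24.6 h: PPV 33.3%, FPR 1.95 -> printed 33 and 1.9
        counts = MatchCounts(1, 2, 0, 1, 17000, 2, 24.6)
        m = compute_metrics(counts)
        assert m.ppv_pct == pytest.approx(100.0 / 3.0)
        assert m.fpr_per_24h == pytest.approx(2 * 24.0 / 24.6)
        assert format_pct(m.ppv_pct) == "33"
        assert format_fpr(m.fpr_per_24h) == "1.9"

    def test_missed_seizure_with_fps(self):
        counts = MatchCounts(0, 3, 1, 1, 17000, 3, 24.0)
        m = compute_metrics(counts)
        assert m.sensitivity_pct == 0.0
        assert m.ppv_pct == 0.0

    def test_no_detections_warns_and_reports_zero_ppv(self):
        counts = MatchCounts(0, 0, 1, 1, 17000, 0, 24.0)
        with pytest.warns(UserWarning, match="PPV"):
            m = compute_metrics(counts)
        assert m.ppv_pct == 0.0

    def test_fpr_scale_consistency(self):
        a = compute_metrics(MatchCounts(1, 4, 0, 1, 1000, 4, 12.0))
        b = compute_metrics(MatchCounts(1, 4, 0, 1, 2000, 4, 24.0))
        assert a.fpr_per_24h == pytest.approx(2 * b.fpr_per_24h)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(MatchCounts(0, 0, 0, 0, 0, 0, 0.0))


class TestFormatting:
    @pytest.mark.parametrize(
        "value, expected", [(1.9512, "1.9"), (2.03, "2.0"), (11.84, "11.8"), (0.9, "0.9"), (0.0, "0.0")]
    )
    def test_fpr_truncates_to_one_decimal(self, value, expected):
        assert format_fpr(value) == expected

    @pytest.mark.parametrize(
        "value, expected", [(60.9, "61"), (25.8, "26"), (99.5, "100"), (100.0, "100"), (33.333, "33")]
    )
    def test_pct_rounds_half_up_to_integer(self, value, expected):
        assert format_pct(value) == expected


class TestMeanMetrics:
    def test_identical_folds_mean_equals_any_fold(self):
        folds = [FoldMetrics(100.0, 2.0, 99.0, 50.0) for _ in range(10)]
        m = mean_metrics(folds)
        assert (m.sensitivity_pct, m.fpr_per_24h, m.ppv_pct) == (100.0, 2.0, 50.0)

    def test_mean_is_full_precision_arithmetic_mean(self):
        fprs = [0.0, 0.0, 0.0, 0.0, 1.9, 2.9, 6.8, 5.8, 0.0, 2.9]
        folds = [FoldMetrics(100.0, f, 99.0, 50.0) for f in fprs]
        assert mean_metrics(folds).fpr_per_24h == pytest.approx(sum(fprs) / 10.0)


class TestOptimizeThreshold:
    def _trace_with_peak(self, peak, where=50):
        v = np.zeros(200)
        v[where] = peak
        return ScoreTrace(values=v, step_s=0.5)

    def test_single_seizure_rule(self):
        ann = SeizureAnnotation(intervals=[(20.0, 40.0)])
        thr = optimize_threshold([(self._trace_with_peak(3.0), ann)])
        assert thr == pytest.approx(3.0 * (1 - 1e-6))

    def test_min_over_seizures(self):
        ann = SeizureAnnotation(intervals=[(20.0, 40.0)])
        training = [
            (self._trace_with_peak(3.0), ann),
            (self._trace_with_peak(2.0), ann),
        ]
        assert optimize_threshold(training) == pytest.approx(2.0 * (1 - 1e-6))

    def test_seizure_without_scores_errors(self):
        trace = ScoreTrace(values=np.ones(10), step_s=0.5)  # covers 0-5 s
        ann = SeizureAnnotation(intervals=[(100.0, 120.0)], recording_id="r9")
        with pytest.raises(ValueError, match="r9"):
            optimize_threshold([(trace, ann)])

    def test_threshold_detects_all_training_seizures(self, small_folds):
        """Self-consistency: the calibrated model redetects its training data."""
        from seizurespec import SeizureDetector

        model = SeizureDetector(
            [f.recording for f in small_folds],
            [f.annotation for f in small_folds],
            RunConfig(),
        )
        res = model.fit()
        for f in small_folds:
            events = res.detect(f.magnitude)
            for onset, offset in f.annotation.intervals:
                assert any(e.overlaps(onset, offset) for e in events)


class TestFpHourHistogram:
    def test_fp_at_half_past_one_pm_lands_in_bin_13(self):
        events = [[_event(1800.0, 1810.0)]]  # 30 min after a 13:00 start
        anns = [SeizureAnnotation()]
        hist = fp_hour_histogram(events, anns, [13 * 3600.0])
        assert hist[13] == 1
        assert hist.sum() == 1

    def test_no_fps_gives_all_zero(self):
        hist = fp_hour_histogram([[]], [SeizureAnnotation()], [0.0])
        assert hist.sum() == 0

    def test_true_positives_not_counted(self):
        ann = SeizureAnnotation(intervals=[(100.0, 200.0)])
        hist = fp_hour_histogram([[_event(150.0, 160.0)]], [ann], [0.0])
        assert hist.sum() == 0


class TestCrossval:
    def test_small_cohort_end_to_end(self, small_folds):
        report = crossval(small_folds, RunConfig(), methods=("scr", "stdev"))
        for method in ("scr", "stdev"):
            assert len(report.per_fold[method]) == 3
            mean = report.mean_row(method)
            assert 0.0 <= mean.sensitivity_pct <= 100.0
            assert mean.fpr_per_24h >= 0.0
        # both methods share fold splits and matching conventions
        assert [m.fold_id for m in report.per_fold["scr"]] == [
            m.fold_id for m in report.per_fold["stdev"]
        ]

    def test_report_tables_and_dict(self, small_folds):
        report = crossval(small_folds, RunConfig(), methods=("scr",))
        df = report.to_frame("scr")
        assert list(df.index)[-1] == "mean"
        printed = report.printed_table("scr")
        assert set(printed.columns) == {
            "SEN (%)",
            "FPR (cases/24 h)",
            "SPEC (%)",
            "PPV (%)",
        }
        doc = report.to_dict()
        assert "scr" in doc["methods"]
        assert len(doc["methods"]["scr"]["fp_hour_histogram"]) == 24

    def test_too_few_folds_rejected(self, small_folds):
        with pytest.raises(ValueError, match="folds"):
            crossval(small_folds[:1], RunConfig())
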