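"""Event-level evaluation: matching, metrics, threshold calibration, k-fold CV.

Conventions
-----------
* A seizure counts as *detected* when at least one detection event overlaps
  its annotated interval; every detection overlapping no seizure is one false
  positive.  Metrics are event-level: sensitivity = detected seizures / total
  seizures, FPR = false-positive events per 24 h of recording, PPV = true
  detections / all detections.
* Specificity needs a count of negatives, so non-seizure time is tiled into
  5-s epochs (the detector's decision cadence); an epoch is a false alarm if
  any false detection overlaps it.
* Thresholds are calibrated on training data only: the largest threshold that
  still detects every training seizure, i.e. the minimum over training
  seizures of the in-ictal maximum score, shaved by a small relative margin.
* Printed tables truncate FPR to one decimal and round percentages half-up to
  integers; full-precision values are always kept alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .detector import (
    DetectionEvent,
    ScoreTrace,
    detect_events,
    scr_trace,
    smooth_scores,
    stdev_trace,
)
from .recording import AcmRecording, MagnitudeSeries, vector_magnitude
from .templates import (
    GdfTemplate,
    SeizureAnnotation,
    average_templates,
    build_gdf,
    interictal_mean_spectrum,
    seizure_mean_spectrum,
)

__all__ = [
    "MatchCounts",
    "FoldMetrics",
    "EvalReport",
    "FoldDataset",
    "match_events",
    "compute_metrics",
    "optimize_threshold",
    "crossval",
    "fp_hour_histogram",
    "mean_metrics",
    "format_fpr",
    "format_pct",
]


# ---------------------------------------------------------------------------
# Matching and metrics


@dataclass
class MatchCounts:
    """Event- and epoch-level tallies for one evaluated recording."""

    tp_events: int
    fp_events: int
    fn_seizures: int
    n_seizures: int
    neg_epochs_total: int
    neg_epochs_flagged: int
    duration_h: float

    def __post_init__(self) -> None:
        if min(
            self.tp_events,
            self.fp_events,
            self.fn_seizures,
            self.n_seizures,
            self.neg_epochs_total,
            self.neg_epochs_flagged,
        ) < 0:
            raise ValueError("counts must be nonnegative")
        if self.neg_epochs_flagged > self.neg_epochs_total:
            raise ValueError("flagged epochs cannot exceed total epochs")
        if self.fn_seizures > self.n_seizures:
            raise ValueError("fn_seizures cannot exceed n_seizures")

    @property
    def detected_seizures(self) -> int:
        return self.n_seizures - self.fn_seizures


def match_events(
    detections: Sequence[DetectionEvent],
    annotation: SeizureAnnotation,
    duration_h: float,
    epoch_s: float = 5.0,
) -> MatchCounts:
    """Match detection events to annotated seizures.

    A seizure is detected if any event overlaps it (closed intervals); a
    detection overlapping no seizure is a false positive.  Non-seizure time is
    tiled into ``epoch_s`` epochs for the specificity denominator.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    intervals = annotation.intervals
    detected = [False] * len(intervals)
    tp = fp = 0
    fp_list: list[DetectionEvent] = []
    for ev in detections:
        hit = False
        for j, (onset, offset) in enumerate(intervals):
            if ev.overlaps(onset, offset):
                detected[j] = True
                hit = True
        if hit:
            tp += 1
        else:
            fp += 1
            fp_list.append(ev)

    duration_s = duration_h * 3600.0
    n_epochs = int(duration_s // epoch_s)
    edges = np.arange(n_epochs + 1) * epoch_s
    starts, ends = edges[:-1], edges[1:]
    negative = np.ones(n_epochs, dtype=bool)
    for onset, offset in intervals:
        negative &= ~((starts < offset) & (ends > onset))
    flagged = np.zeros(n_epochs, dtype=bool)
    for ev in fp_list:
        flagged |= (starts < ev.offset_s) & (ends > ev.onset_s)
    flagged &= negative

    return MatchCounts(
        tp_events=tp,
        fp_events=fp,
        fn_seizures=sum(1 for d in detected if not d),
        n_seizures=len(intervals),
        neg_epochs_total=int(negative.sum()),
        neg_epochs_flagged=int(flagged.sum()),
        duration_h=duration_h,
    )


@dataclass
class FoldMetrics:
    """The four headline metrics for one fold (full precision)."""

    sensitivity_pct: float  # NaN when the fold holds no seizures
    fpr_per_24h: float
    specificity_pct: float
    ppv_pct: float
    counts: MatchCounts | None = None
    fold_id: str = ""
    threshold: float = float("nan")

    def as_row(self) -> dict:
        return {
            "fold": self.fold_id,
            "sen_pct": self.sensitivity_pct,
            "fpr_per_24h": self.fpr_per_24h,
            "spec_pct": self.specificity_pct,
            "ppv_pct": self.ppv_pct,
            "threshold": self.threshold,
        }


def compute_metrics(counts: MatchCounts, fold_id: str = "") -> FoldMetrics:
    """Sensitivity / FPR / specificity / PPV from matched counts."""
    if counts.duration_h <= 0:
        raise ValueError("duration_h must be positive")
    if counts.n_seizures > 0:
        sen = 100.0 * counts.detected_seizures / counts.n_seizures
    else:
        sen = float("nan")  # undefined without positives
    fpr = counts.fp_events * 24.0 / counts.duration_h
    if counts.neg_epochs_total > 0:
        spec = (
            100.0
            * (counts.neg_epochs_total - counts.neg_epochs_flagged)
            / counts.neg_epochs_total
        )
    else:
        spec = float("nan")
    denom = counts.tp_events + counts.fp_events
    if denom == 0:
        warnings.warn("PPV undefined (no detections); reporting 0", stacklevel=2)
        ppv = 0.0
    else:
        ppv = 100.0 * counts.tp_events / denom
    return FoldMetrics(
        sensitivity_pct=sen,
        fpr_per_24h=fpr,
        specificity_pct=spec,
        ppv_pct=ppv,
        counts=counts,
        fold_id=fold_id,
    )


def mean_metrics(per_fold: Sequence[FoldMetrics]) -> FoldMetrics:
    """Arithmetic mean row across folds (full precision, NaNs excluded)."""
    if not per_fold:
        raise ValueError("need at least one fold")

    def _mean(values: list[float]) -> float:
        vals = [v for v in values if not math.isnan(v)]
        return sum(vals) / len(vals) if vals else float("nan")

    return FoldMetrics(
        sensitivity_pct=_mean([m.sensitivity_pct for m in per_fold]),
        fpr_per_24h=_mean([m.fpr_per_24h for m in per_fold]),
        specificity_pct=_mean([m.specificity_pct for m in per_fold]),
        ppv_pct=_mean([m.ppv_pct for m in per_fold]),
        fold_id="mean",
    )


def format_fpr(value: float) -> str:
    """FPR printed truncated to one decimal (1.95 -> '1.9')."""
    if math.isnan(value):
        return "n/a"
    return f"{math.floor(value * 10 + 1e-9) / 10:.1f}"


def format_pct(value: float) -> str:
    """Percentages printed rounded half-up to integers (60.9 -> '61')."""
    if math.isnan(value):
        return "n/a"
    return str(int(math.floor(value + 0.5 + 1e-9)))


# ---------------------------------------------------------------------------
# Threshold calibration


def optimize_threshold(
    training: Sequence[tuple[ScoreTrace, SeizureAnnotation]],
    margin: float = 1e-6,
) -> float:
    """Largest threshold that still detects every training seizure.

    Computed as the minimum over training seizures of the maximum score
    stamped inside the seizure interval, shaved by a relative margin so the
    strict comparison keeps 100% training sensitivity while rejecting as many
    false positives as possible.
    """
    maxima: list[float] = []
    for trace, annotation in training:
        for onset, offset in annotation.intervals:
            peak = trace.max_in_interval(onset, offset)
            if math.isnan(peak):
                raise ValueError(
                    f"no scores inside seizure ({onset:g}, {offset:g}) s of "
                    f"recording {annotation.recording_id!r}"
                )
            maxima.append(peak)
    if not maxima:
        raise ValueError("training data holds no seizures")
    floor = min(maxima)
    return floor - abs(floor) * margin


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class FoldDataset:
    """One cross-validation fold: a recording plus its annotation."""

    recording: AcmRecording
    annotation: SeizureAnnotation
    fold_id: str = ""

    _magnitude: MagnitudeSeries | None = field(default=None, repr=False)

    @property
    def magnitude(self) -> MagnitudeSeries:
        if self._magnitude is None:
            self._magnitude = vector_magnitude(self.recording)
        return self._magnitude

    @property
    def duration_h(self) -> float:
        return self.recording.duration_h


@dataclass
class EvalReport:
    """Per-fold and mean metrics for each detection method."""

    per_fold: dict[str, list[FoldMetrics]]
    detections: dict[str, list[list[DetectionEvent]]]
    start_clocks_s: list[float]
    annotations: list[SeizureAnnotation]
    config: RunConfig

    def mean_row(self, method: str) -> FoldMetrics:
        return mean_metrics(self.per_fold[method])

    def to_frame(self, method: str) -> pd.DataFrame:
        rows = [m.as_row() for m in self.per_fold[method]]
        rows.append(self.mean_row(method).as_row())
        return pd.DataFrame(rows).set_index("fold")

    def printed_table(self, method: str) -> pd.DataFrame:
        """Table in the published presentation style (truncated/rounded)."""
        df = self.to_frame(method)
        out = pd.DataFrame(index=df.index)
        out["SEN (%)"] = df["sen_pct"].map(format_pct)
        out["FPR (cases/24 h)"] = df["fpr_per_24h"].map(format_fpr)
        out["SPEC (%)"] = df["spec_pct"].map(format_pct)
        out["PPV (%)"] = df["ppv_pct"].map(format_pct)
        return out

    def fp_histogram(self, method: str) -> np.ndarray:
        return fp_hour_histogram(
            self.detections[method], self.annotations, self.start_clocks_s
        )

    def to_dict(self) -> dict:
        doc: dict = {"config": self.config.to_dict(), "methods": {}}
        for method, metrics in self.per_fold.items():
            doc["methods"][method] = {
                "per_fold": [m.as_row() for m in metrics],
                "mean": self.mean_row(method).as_row(),
                "printed_mean": {
                    "sen_pct": format_pct(self.mean_row(method).sensitivity_pct),
                    "fpr_per_24h": format_fpr(self.mean_row(method).fpr_per_24h),
                    "spec_pct": format_pct(self.mean_row(method).specificity_pct),
                    "ppv_pct": format_pct(self.mean_row(method).ppv_pct),
                },
                "fp_hour_histogram": self.fp_histogram(method).tolist(),
            }
        return doc


def _fit_fold_gdf(
    training: Sequence[FoldDataset], config: RunConfig
) -> GdfTemplate:
    spec = config.window_spec()
    ictal = []
    for ds in training:
        for j, interval in enumerate(ds.annotation.intervals):
            ictal.append(
                seizure_mean_spectrum(
                    ds.magnitude,
                    interval,
                    spec,
                    f_max_hz=config.f_max_hz,
                    mode=config.spectrum_mode,
                    exclude_dc=config.exclude_dc,
                    template_id=f"{ds.fold_id}:{j}",
                )
            )
    gtcs_template = average_templates(ictal, source="gtcs")
    interictal_template = interictal_mean_spectrum(
        ((ds.magnitude, ds.annotation) for ds in training),
        spec,
        f_max_hz=config.f_max_hz,
        mode=config.spectrum_mode,
        exclude_dc=config.exclude_dc,
    )
    return build_gdf(gtcs_template, interictal_template, eps_floor=config.eps_floor)


def _spectral_score(
    ds: FoldDataset, gdf: GdfTemplate, config: RunConfig
) -> ScoreTrace:
    raw = scr_trace(
        ds.magnitude,
        gdf,
        config.window_spec(),
        mode=config.spectrum_mode,
        exclude_dc=config.exclude_dc,
    )
    return smooth_scores(raw, config.smooth_k)


def crossval(
    datasets: Sequence[FoldDataset],
    config: RunConfig = RunConfig(),
    methods: Sequence[str] = ("scr", "stdev"),
) -> EvalReport:
    """Leave-one-fold-out evaluation of the spectral and temporal detectors.

    For each fold the GDF is rebuilt from the remaining folds' ictal and
    interictal data, the threshold is calibrated on those training folds, and
    the held-out fold is scored and matched.  Both methods share fold splits,
    score clock, event merging and matching, so the comparison is paired.
    """
    k = len(datasets)
    if k < 2:
        raise ValueError("cross-validation needs at least 2 folds")
    for ds in datasets:
        if len(ds.magnitude) == 0:
            raise ValueError(f"fold {ds.fold_id!r} has no test data")

    per_fold: dict[str, list[FoldMetrics]] = {m: [] for m in methods}
    detections: dict[str, list[list[DetectionEvent]]] = {m: [] for m in methods}

    # Stdev traces do not depend on the fold, compute once.
    stdev_traces = (
        {
            id(ds): stdev_trace(ds.magnitude, config.stdev_n, config.stdev_step)
            for ds in datasets
        }
        if "stdev" in methods
        else {}
    )

    for i, test in enumerate(datasets):
        training = [ds for j, ds in enumerate(datasets) if j != i]
        fold_id = test.fold_id or f"fold{i + 1}"

        if "scr" in methods:
            gdf = _fit_fold_gdf(training, config)
            train_traces = [
                (_spectral_score(ds, gdf, config), ds.annotation) for ds in training
            ]
            threshold = optimize_threshold(train_traces, config.threshold_margin)
            events = detect_events(
                _spectral_score(test, gdf, config), threshold, config.merge_gap_s
            )
            counts = match_events(
                events, test.annotation, test.duration_h, config.epoch_s
            )
            m = compute_metrics(counts, fold_id)
            m.threshold = threshold
            per_fold["scr"].append(m)
            detections["scr"].append(events)

        if "stdev" in methods:
            train_traces = [
                (stdev_traces[id(ds)], ds.annotation) for ds in training
            ]
            threshold = optimize_threshold(train_traces, config.threshold_margin)
            events = detect_events(
                stdev_traces[id(test)], threshold, config.merge_gap_s
            )
            counts = match_events(
                events, test.annotation, test.duration_h, config.epoch_s
            )
            m = compute_metrics(counts, fold_id)
            m.threshold = threshold
            per_fold["stdev"].append(m)
            detections["stdev"].append(events)

    return EvalReport(
        per_fold=per_fold,
        detections=detections,
        start_clocks_s=[ds.recording.start_clock_s for ds in datasets],
        annotations=[ds.annotation for ds in datasets],
        config=config,
    )


# ---------------------------------------------------------------------------
# Hour-of-day false-positive histogram


def fp_hour_histogram(
    detections_by_fold: Sequence[Sequence[DetectionEvent]],
    annotations: Sequence[SeizureAnnotation],
    start_clocks_s: Sequence[float],
) -> np.ndarray:
    """24-bin histogram of false-positive onsets by clock hour."""
    hist = np.zeros(24, dtype=int)
    for events, annotation, start_clock in zip(
        detections_by_fold, annotations, start_clocks_s
    ):
        for ev in events:
            if any(ev.overlaps(a, b) for a, b in annotation.intervals):
                continue
            hour = int(((start_clock + ev.onset_s) % 86400.0) // 3600.0)
            hist[hour] += 1
    return hist
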