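"""Score traces and threshold-based event detection.

Two detectors share one event machinery:

* the spectral score SCR — the GDF-weighted average of each 1-s window's
  magnitude spectrum, normalized by the window's total spectral magnitude, so
  it is invariant to the overall amplitude of movement and responds only to
  spectral shape; and
* the temporal baseline Stdev — the population standard deviation of the ACM
  signal over 5-s windows, which scales linearly with movement amplitude.

Both are emitted every 0.5 s with the default configuration; detection
compares the 10-score (5-s) trailing mean of the SCR, or the Stdev directly,
against a threshold, and maximal supra-threshold runs become events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .recording import MagnitudeSeries, WindowSpec, window_spectra, window_start_indices
from .templates import GdfTemplate

__all__ = [
    "ScoreTrace",
    "DetectionEvent",
    "DetectorConfig",
    "scr_trace",
    "smooth_scores",
    "stdev_trace",
    "detect_events",
]


@dataclass
class ScoreTrace:
    """Detector score sampled on a regular grid.

    Scores are stamped at the START time of the window they summarize
    (0-based, half-open window spans).
    """

    values: np.ndarray
    step_s: float = 0.5
    t0_s: float = 0.0
    method: str = "scr"  # 'scr' | 'scr_smoothed' | 'stdev'

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not self.step_s > 0:
            raise ValueError("step_s must be positive")
        if self.method not in ("scr", "scr_smoothed", "stdev"):
            raise ValueError(f"unknown method {self.method!r}")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + self.step_s * np.arange(len(self))

    def max_in_interval(self, onset_s: float, offset_s: float) -> float:
        """Largest score stamped in ``[onset_s, offset_s)``; NaN if none."""
        t = self.times_s
        mask = (t >= onset_s) & (t < offset_s)
        if not mask.any():
            return float("nan")
        return float(self.values[mask].max())


@dataclass
class DetectionEvent:
    """One supra-threshold run (possibly merged across short gaps)."""

    onset_s: float
    offset_s: float
    peak_score: float
    method: str = "scr_smoothed"

    def __post_init__(self) -> None:
        if self.offset_s < self.onset_s:
            raise ValueError("offset_s must be >= onset_s")

    def overlaps(self, onset_s: float, offset_s: float) -> bool:
        return self.onset_s <= offset_s and self.offset_s >= onset_s


@dataclass(frozen=True)
class DetectorConfig:
    """Threshold and event-merging parameters."""

    threshold: float
    smooth_k: int = 10
    merge_gap_s: float = 30.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.smooth_k < 1:
            raise ValueError("smooth_k must be >= 1")
        if self.merge_gap_s < 0:
            raise ValueError("merge_gap_s must be >= 0")


def scr_trace(
    series: MagnitudeSeries,
    gdf: GdfTemplate,
    spec: WindowSpec = WindowSpec(),
    mode: str = "magnitude",
    exclude_dc: bool = False,
) -> ScoreTrace:
    """Seizure-correlated ratio of every analysis window.

    Each score is ``sum(GDF * X) / sum(X)`` over the window's magnitude
    spectrum X — a convex combination of GDF weights, hence bounded by the
    smallest and largest weight and invariant to positive scaling of the
    signal.  All-zero windows score 0 by convention.
    """
    starts = window_start_indices(len(series), spec)
    step_s = spec.step_samples / series.sample_rate
    if starts.size == 0:
        return ScoreTrace(values=np.empty(0), step_s=step_s, method="scr")
    view = sliding_window_view(series.values, spec.length_samples)[starts]
    spectra = window_spectra(view, spec, series.sample_rate, gdf.f_max_hz, mode)
    if exclude_dc:
        spectra = spectra.copy()
        spectra[:, 0] = 0.0
    denom = spectra.sum(axis=1)
    num = spectra @ gdf.weights
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return ScoreTrace(values=scores, step_s=step_s, t0_s=0.0, method="scr")


def smooth_scores(trace: ScoreTrace, k: int = 10) -> ScoreTrace:
    """Trailing (causal) moving mean over ``k`` scores.

    Only full averages are emitted: the output starts at the k-th input score
    and is stamped at that score's time, matching a real-time alerting device
    that reports once its 5-s buffer has filled.  A trace shorter than ``k``
    yields an empty (valid) trace.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(trace) < k:
        return ScoreTrace(
            values=np.empty(0),
            step_s=trace.step_s,
            t0_s=trace.t0_s,
            method="scr_smoothed" if trace.method.startswith("scr") else trace.method,
        )
    kernel = np.full(k, 1.0 / k)
    smoothed = np.convolve(trace.values, kernel, mode="valid")
    return ScoreTrace(
        values=smoothed,
        step_s=trace.step_s,
        t0_s=trace.t0_s + (k - 1) * trace.step_s,
        method="scr_smoothed" if trace.method.startswith("scr") else trace.method,
    )


def stdev_trace(
    series: MagnitudeSeries, n: int = 500, step: int = 50
) -> ScoreTrace:
    """Population standard deviation over sliding ``n``-sample windows.

    Defaults (n=500, step=50 at 100 Hz) give a 5-s window advanced by 0.5 s,
    putting the temporal baseline on the same score clock as the SCR.  The
    divisor is N (population form), not N-1.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    x = series.values
    step_s = step / series.sample_rate
    if x.size < n:
        return ScoreTrace(values=np.empty(0), step_s=step_s, method="stdev")
    starts = np.arange(0, x.size - n + 1, step)
    view = sliding_window_view(x, n)
    out = np.empty(starts.size)
    # chunked exact two-pass: mean, then mean squared deviation
    chunk = max(1, 4_000_000 // n)
    for lo in range(0, starts.size, chunk):
        w = view[starts[lo : lo + chunk]]
        m = w.mean(axis=1)
        out[lo : lo + chunk] = np.sqrt(((w - m[:, None]) ** 2).mean(axis=1))
    return ScoreTrace(values=out, step_s=step_s, t0_s=0.0, method="stdev")


def detect_events(
    trace: ScoreTrace, threshold: float, merge_gap_s: float = 30.0
) -> list[DetectionEvent]:
    """Maximal runs of scores strictly above threshold, merged across gaps.

    Consecutive events separated by at most ``merge_gap_s`` are merged so one
    clinical event with brief sub-threshold dips counts as one detection.
    Event onset/offset are the first/last supra-threshold score times.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    above = trace.values > threshold
    if not above.any():
        return []
    t = trace.times_s
    edges = np.diff(above.astype(np.int8))
    run_starts = np.flatnonzero(edges == 1) + 1
    run_ends = np.flatnonzero(edges == -1)  # inclusive end index
    if above[0]:
        run_starts = np.concatenate([[0], run_starts])
    if above[-1]:
        run_ends = np.concatenate([run_ends, [len(above) - 1]])

    events: list[DetectionEvent] = []
    for s, e in zip(run_starts, run_ends):
        peak = float(trace.values[s : e + 1].max())
        if events and t[s] - events[-1].offset_s <= merge_gap_s:
            prev = events[-1]
            events[-1] = DetectionEvent(
                onset_s=prev.onset_s,
                offset_s=float(t[e]),
                peak_score=max(prev.peak_score, peak),
                method=prev.method,
            )
        else:
            events.append(
                DetectionEvent(
                    onset_s=float(t[s]),
                    offset_s=float(t[e]),
                    peak_score=peak,
                    method=trace.method,
                )
            )
    return events
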