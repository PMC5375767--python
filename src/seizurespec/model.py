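"""Model/Results front for the spectral seizure detector.

``SeizureDetector`` is constructed from labeled training recordings; ``fit``
estimates the ictal and interictal spectral templates, their ratio (the GDF
weight function) and the detection threshold, returning a
``SeizureDetectorResults`` that scores and detects on new recordings and
prints a ``summary()`` table.

Example
-------
>>> from seizurespec import SimConfig, simulate_cohort, SeizureDetector
>>> cohort = simulate_cohort(SimConfig(seed=7), k=4)
>>> model = SeizureDetector(
...     [rec for rec, _ in cohort[:3]], [ann for _, ann in cohort[:3]]
... )
>>> res = model.fit()
>>> events = res.detect(cohort[3][0])
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import RunConfig
from .detector import (
    DetectionEvent,
    ScoreTrace,
    detect_events,
    scr_trace,
    smooth_scores,
)
from .evaluation import FoldDataset, optimize_threshold
from .recording import AcmRecording, MagnitudeSeries, read_recording, vector_magnitude
from .templates import (
    GdfTemplate,
    SeizureAnnotation,
    SpectralTemplate,
    average_templates,
    build_gdf,
    interictal_mean_spectrum,
    read_annotation,
    seizure_mean_spectrum,
    write_gdf,
)

__all__ = ["SeizureDetector", "SeizureDetectorResults"]


class SeizureDetector:
    """Spectral GTCS detector estimated from labeled recordings.

    Parameters
    ----------
    recordings : sequence of AcmRecording
        Training recordings.
    annotations : sequence of SeizureAnnotation
        Seizure intervals for each recording, aligned with ``recordings``.
    config : RunConfig
        Windowing, spectrum and detection parameters.
    """

    def __init__(
        self,
        recordings: Sequence[AcmRecording],
        annotations: Sequence[SeizureAnnotation],
        config: RunConfig = RunConfig(),
    ) -> None:
        if len(recordings) != len(annotations):
            raise ValueError("recordings and annotations must align")
        if not recordings:
            raise ValueError("need at least one training recording")
        self.config = config
        self.data = [
            FoldDataset(recording=rec, annotation=ann, fold_id=rec.subject_id or str(i))
            for i, (rec, ann) in enumerate(zip(recordings, annotations))
        ]

    @classmethod
    def from_files(
        cls,
        recording_paths: Sequence[str | Path],
        annotation_paths: Sequence[str | Path],
        config: RunConfig = RunConfig(),
    ) -> "SeizureDetector":
        recs = [read_recording(p) for p in recording_paths]
        anns = [read_annotation(p) for p in annotation_paths]
        return cls(recs, anns, config)

    def fit(self) -> "SeizureDetectorResults":
        """Estimate templates, GDF weights and the detection threshold."""
        cfg = self.config
        spec = cfg.window_spec()
        ictal: list[SpectralTemplate] = []
        for ds in self.data:
            for j, interval in enumerate(ds.annotation.intervals):
                ictal.append(
                    seizure_mean_spectrum(
                        ds.magnitude,
                        interval,
                        spec,
                        f_max_hz=cfg.f_max_hz,
                        mode=cfg.spectrum_mode,
                        exclude_dc=cfg.exclude_dc,
                        template_id=f"{ds.fold_id}:{j}",
                    )
                )
        if not ictal:
            raise ValueError("training data holds no annotated seizures")
        gtcs_template = average_templates(ictal, source="gtcs")
        interictal_template = interictal_mean_spectrum(
            ((ds.magnitude, ds.annotation) for ds in self.data),
            spec,
            f_max_hz=cfg.f_max_hz,
            mode=cfg.spectrum_mode,
            exclude_dc=cfg.exclude_dc,
        )
        gdf = build_gdf(gtcs_template, interictal_template, eps_floor=cfg.eps_floor)

        results = SeizureDetectorResults(
            model=self,
            gdf=gdf,
            gtcs_template=gtcs_template,
            interictal_template=interictal_template,
            per_seizure_templates=ictal,
            threshold=float("nan"),
        )
        train_traces = [
            (results.score(ds.magnitude), ds.annotation) for ds in self.data
        ]
        results.threshold = optimize_threshold(train_traces, cfg.threshold_margin)
        return results


@dataclass
class SeizureDetectorResults:
    """Fitted templates, GDF weights and calibrated threshold."""

    model: SeizureDetector
    gdf: GdfTemplate
    gtcs_template: SpectralTemplate
    interictal_template: SpectralTemplate
    per_seizure_templates: list[SpectralTemplate]
    threshold: float

    @property
    def config(self) -> RunConfig:
        return self.model.config

    # -- application --------------------------------------------------------

    def score(self, data: AcmRecording | MagnitudeSeries) -> ScoreTrace:
        """Smoothed SCR trace of a recording or magnitude series."""
        series = data if isinstance(data, MagnitudeSeries) else vector_magnitude(data)
        cfg = self.config
        raw = scr_trace(
            series,
            self.gdf,
            cfg.window_spec(),
            mode=cfg.spectrum_mode,
            exclude_dc=cfg.exclude_dc,
        )
        return smooth_scores(raw, cfg.smooth_k)

    def detect(
        self, data: AcmRecording | MagnitudeSeries, threshold: float | None = None
    ) -> list[DetectionEvent]:
        """Detected events on new data using the calibrated threshold."""
        trace = self.score(data)
        thr = self.threshold if threshold is None else threshold
        return detect_events(trace, thr, self.config.merge_gap_s)

    def save_gdf(self, path: str | Path) -> None:
        write_gdf(self.gdf, path)

    # -- reporting ----------------------------------------------------------

    def peak_band_hz(self) -> int:
        """Frequency bin carrying the largest GDF weight."""
        return int(np.argmax(self.gdf.weights))

    def summary(self) -> str:
        cfg = self.config
        n_seiz = len(self.per_seizure_templates)
        w = self.gdf.weights
        order = np.argsort(w)[::-1][:5]
        lines = [
            "Spectral GTCS detector (GDF / SCR)",
            "=" * 50,
            f"Training recordings:      {len(self.model.data)}",
            f"Training seizures:        {n_seiz}",
            f"Ictal windows:            {self.gtcs_template.n_windows}",
            f"Interictal windows:       {self.interictal_template.n_windows}",
            f"Window: {cfg.window_n} samples, {cfg.overlap_fraction:.0%} overlap, "
            f"{cfg.taper} taper, {cfg.spectrum_mode} spectra to {cfg.f_max_hz} Hz",
            f"Smoothing: trailing mean of {cfg.smooth_k} scores",
            f"Detection threshold:      {self.threshold:.4g}",
            f"Peak GDF weight:          {w.max():.4g} at {self.peak_band_hz()} Hz",
            "-" * 50,
            "Top GDF weights (Hz : weight):",
        ]
        lines += [f"  {int(b):>4d} : {w[b]:.4g}" for b in order]
        return "\n".join(lines)

    # -- plotting ------------------------------------------------------------

    def plot_gdf(self, ax=None):
        """Bar plot of GDF weights per frequency (log scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(self.gdf.bins_hz, self.gdf.weights, width=0.8)
        ax.set_yscale("log")
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("GDF weight")
        return ax

    def plot_scores(self, data: AcmRecording | MagnitudeSeries, ax=None):
        """Smoothed SCR trace with the calibrated threshold line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        trace = self.score(data)
        ax.plot(trace.times_s, trace.values, lw=0.7)
        ax.axhline(self.threshold, color="r", ls="--", lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("smoothed SCR")
        return ax
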