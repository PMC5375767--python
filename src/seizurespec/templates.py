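"""Ictal / interictal spectral templates and the GTCS-dependent weight function.

Template construction follows a template-matching recipe: per-seizure mean
magnitude spectra are normalized to unit sum, averaged across seizures into an
ictal template, an interictal template is pooled from all non-seizure windows,
and the GDF (GTCS-dependent spectral weight function) is their per-frequency
ratio.  A GDF weight of 1 at a frequency means seizure and normal movement
carry identical (relative) power there; weights above 1 mark frequencies where
seizure movement is over-represented — empirically the 4–25 Hz clonic band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .recording import (
    MagnitudeSeries,
    WindowSpec,
    window_spectra,
    window_start_indices,
    sliding_window_view,
)

__all__ = [
    "SeizureAnnotation",
    "SpectralTemplate",
    "GdfTemplate",
    "read_annotation",
    "write_annotation",
    "seizure_mean_spectrum",
    "average_templates",
    "interictal_mean_spectrum",
    "build_gdf",
    "read_gdf",
    "write_gdf",
]

DEFAULT_EPS_FLOOR = 1e-12


@dataclass
class SeizureAnnotation:
    """Labeled seizure intervals for one recording.

    ``intervals`` is a list of ``(onset_s, offset_s)`` pairs, in seconds from
    the start of the recording, sorted and non-overlapping.
    """

    intervals: list[tuple[float, float]] = field(default_factory=list)
    recording_id: str = ""
    label: str = "GTCS"

    def __post_init__(self) -> None:
        self.intervals = [(float(a), float(b)) for a, b in self.intervals]
        prev_end = -np.inf
        for onset, offset in self.intervals:
            if not offset > onset:
                raise ValueError(f"interval ({onset}, {offset}) has nonpositive duration")
            if onset < prev_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_end = offset

    def __len__(self) -> int:
        return len(self.intervals)

    def durations_s(self) -> list[float]:
        return [b - a for a, b in self.intervals]


def read_annotation(path: str | Path) -> SeizureAnnotation:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    intervals = [(iv["onset_s"], iv["offset_s"]) for iv in doc.get("intervals", [])]
    return SeizureAnnotation(
        intervals=intervals, recording_id=doc.get("recording_id", "")
    )


def write_annotation(ann: SeizureAnnotation, path: str | Path) -> None:
    doc = {
        "recording_id": ann.recording_id,
        "intervals": [
            {"onset_s": a, "offset_s": b, "label": ann.label}
            for a, b in ann.intervals
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


@dataclass
class SpectralTemplate:
    """Unit-sum average magnitude spectrum (ictal or interictal)."""

    values: np.ndarray
    source: str = "gtcs"  # 'gtcs' | 'interictal'
    n_windows: int = 0
    template_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("template values must be one-dimensional")
        if float(self.values.min(initial=0.0)) < 0:
            raise ValueError("template values must be nonnegative")
        total = float(self.values.sum())
        if self.values.size and abs(total - 1.0) > 1e-9:
            raise ValueError(f"template must sum to 1 (got {total!r})")
        if self.source not in ("gtcs", "interictal"):
            raise ValueError("source must be 'gtcs' or 'interictal'")

    @property
    def f_max_hz(self) -> int:
        return self.values.size - 1

    @property
    def bins_hz(self) -> np.ndarray:
        return np.arange(self.values.size)


@dataclass
class GdfTemplate:
    """Positive per-frequency weights: ictal template over interictal template."""

    weights: np.ndarray
    eps_floor: float = DEFAULT_EPS_FLOOR
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be one-dimensional")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.weights.size and float(self.weights.min()) <= 0:
            raise ValueError("weights must be strictly positive")

    @property
    def f_max_hz(self) -> int:
        return self.weights.size - 1

    @property
    def bins_hz(self) -> np.ndarray:
        return np.arange(self.weights.size)


# ---------------------------------------------------------------------------
# Template construction


def _normalize(mean_spectrum: np.ndarray) -> np.ndarray:
    total = float(mean_spectrum.sum())
    if total <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return mean_spectrum / total


def _interval_to_slice(
    interval: tuple[float, float], sample_rate: float, n_samples: int
) -> tuple[int, int]:
    onset, offset = interval
    lo = max(int(round(onset * sample_rate)), 0)
    hi = min(int(round(offset * sample_rate)), n_samples)
    return lo, hi


def seizure_mean_spectrum(
    series: MagnitudeSeries,
    interval: tuple[float, float],
    spec: WindowSpec = WindowSpec(),
    f_max_hz: int = 50,
    mode: str = "magnitude",
    exclude_dc: bool = False,
    template_id: str = "",
) -> SpectralTemplate:
    """Unit-sum mean spectrum of one annotated seizure segment.

    Windows the ictal samples, averages the per-window magnitude spectra and
    divides by the grand total, so the template sums to 1.
    """
    lo, hi = _interval_to_slice(interval, series.sample_rate, len(series))
    segment = series.values[lo:hi]
    starts = window_start_indices(segment.size, spec)
    if starts.size == 0:
        raise ValueError(
            f"segment too short: interval {interval} holds {segment.size} samples, "
            f"fewer than one {spec.length_samples}-sample window"
        )
    view = sliding_window_view(segment, spec.length_samples)[starts]
    spectra = window_spectra(view, spec, series.sample_rate, f_max_hz, mode)
    mean = spectra.mean(axis=0)
    if exclude_dc:
        mean = mean.copy()
        mean[0] = 0.0
    return SpectralTemplate(
        values=_normalize(mean),
        source="gtcs",
        n_windows=int(starts.size),
        template_id=template_id,
    )


def average_templates(
    templates: Sequence[SpectralTemplate], source: str | None = None
) -> SpectralTemplate:
    """Unweighted element-wise mean of unit-sum templates (itself unit-sum)."""
    if not templates:
        raise ValueError("need at least one template")
    sources = {t.source for t in templates}
    if len(sources) > 1:
        raise ValueError(f"cannot average templates of mixed sources {sources}")
    if source is not None and sources != {source}:
        raise ValueError(f"expected source {source!r}, got {sources}")
    sizes = {t.values.size for t in templates}
    if len(sizes) > 1:
        raise ValueError("templates must share one frequency grid")
    mean = np.mean([t.values for t in templates], axis=0)
    return SpectralTemplate(
        values=mean,
        source=templates[0].source,
        n_windows=sum(t.n_windows for t in templates),
        template_id="+".join(t.template_id for t in templates if t.template_id),
    )


def _interictal_window_mask(
    n_samples: int,
    sample_rate: float,
    annotation: SeizureAnnotation,
    spec: WindowSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and keep-mask of windows clear of every seizure interval.

    Windows straddling a seizure boundary are excluded (they belong to neither
    class cleanly).
    """
    starts = window_start_indices(n_samples, spec)
    keep = np.ones(starts.size, dtype=bool)
    for onset, offset in annotation.intervals:
        lo, hi = onset * sample_rate, offset * sample_rate
        # window [s, s+N) intersects [lo, hi) ?
        keep &= ~((starts < hi) & (starts + spec.length_samples > lo))
    return starts, keep


def interictal_mean_spectrum(
    recordings: Iterable[tuple[MagnitudeSeries, SeizureAnnotation]],
    spec: WindowSpec = WindowSpec(),
    f_max_hz: int = 50,
    mode: str = "magnitude",
    exclude_dc: bool = False,
) -> SpectralTemplate:
    """Pooled unit-sum mean spectrum of all non-seizure windows."""
    total = None
    count = 0
    for series, annotation in recordings:
        starts, keep = _interictal_window_mask(
            len(series), series.sample_rate, annotation, spec
        )
        starts = starts[keep]
        if starts.size == 0:
            continue
        view = sliding_window_view(series.values, spec.length_samples)[starts]
        spectra = window_spectra(view, spec, series.sample_rate, f_max_hz, mode)
        s = spectra.sum(axis=0)
        total = s if total is None else total + s
        count += int(starts.size)
    if count == 0:
        raise ValueError("no interictal windows available")
    mean = total / count
    if exclude_dc:
        mean[0] = 0.0
    return SpectralTemplate(
        values=_normalize(mean), source="interictal", n_windows=count
    )


def build_gdf(
    gtcs_template: SpectralTemplate,
    interictal_template: SpectralTemplate,
    eps_floor: float = DEFAULT_EPS_FLOOR,
) -> GdfTemplate:
    """Per-frequency ratio of ictal to interictal templates.

    Both numerator and denominator are floored at ``eps_floor``, so empty
    interictal bins cannot produce infinities, every weight is strictly
    positive, and a template divided by itself gives exactly 1 in every bin
    (including bins that are zero in both).
    """
    if gtcs_template.values.size != interictal_template.values.size:
        raise ValueError("templates must share one frequency grid")
    if not eps_floor > 0:
        raise ValueError("eps_floor must be positive")
    weights = np.maximum(gtcs_template.values, eps_floor) / np.maximum(
        interictal_template.values, eps_floor
    )
    return GdfTemplate(
        weights=weights,
        eps_floor=eps_floor,
        provenance=[
            t.template_id or t.source
            for t in (gtcs_template, interictal_template)
        ],
    )


# ---------------------------------------------------------------------------
# JSON round-trips


def write_gdf(gdf: GdfTemplate, path: str | Path) -> None:
    doc = {
        "f_max_hz": gdf.f_max_hz,
        "bins_hz": gdf.bins_hz.tolist(),
        "values": gdf.weights.tolist(),
        "eps_floor": gdf.eps_floor,
        "provenance": gdf.provenance,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def read_gdf(path: str | Path, f_max_hz: int | None = None) -> GdfTemplate:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    values = np.asarray(doc["values"], dtype=float)
    declared = int(doc["f_max_hz"])
    if values.size != declared + 1:
        raise ValueError(
            f"GDF file declares f_max {declared} Hz but holds {values.size} bins"
        )
    if f_max_hz is not None and declared != f_max_hz:
        raise ValueError(f"expected f_max {f_max_hz} Hz, file has {declared}")
    return GdfTemplate(
        weights=values,
        eps_floor=float(doc.get("eps_floor", DEFAULT_EPS_FLOOR)),
        provenance=list(doc.get("provenance", [])),
    )


def write_template(template: SpectralTemplate, path: str | Path) -> None:
    doc = {
        "f_max_hz": template.f_max_hz,
        "bins_hz": template.bins_hz.tolist(),
        "values": template.values.tolist(),
        "source": template.source,
        "n_windows": template.n_windows,
        "template_id": template.template_id,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def read_template(path: str | Path) -> SpectralTemplate:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    values = np.asarray(doc["values"], dtype=float)
    if values.size != int(doc["f_max_hz"]) + 1:
        raise ValueError("template bin count does not match declared f_max")
    return SpectralTemplate(
        values=values,
        source=doc.get("source", "gtcs"),
        n_windows=int(doc.get("n_windows", 0)),
        template_id=doc.get("template_id", ""),
    )
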