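"""Accelerometer recordings, vector-magnitude preprocessing and windowed spectra.

The analyzed signal throughout the package is the *ACM* series: the vector
magnitude ``sqrt(x^2 + y^2 + z^2)`` of a 3-axis wrist accelerometer sampled at
100 samples/s over a +/-8 g range.  Short-time spectra are taken over 1-s
Hamming windows with 50% overlap, yielding magnitude spectra on an integer
frequency grid 0..50 Hz (51 bins for the default configuration).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "SENSOR_RANGE_G",
    "AcmRecording",
    "MagnitudeSeries",
    "WindowSpec",
    "Spectrum",
    "SchemaError",
    "read_recording",
    "write_recording",
    "vector_magnitude",
    "segment_windows",
    "window_start_indices",
    "window_spectrum",
    "window_spectra",
]

#: Stated dynamic range of the wrist sensor, in g.
SENSOR_RANGE_G = 8.0


class SchemaError(ValueError):
    """Raised when an input file violates the expected schema."""


@dataclass
class AcmRecording:
    """A uniformly sampled 3-axis acceleration stream.

    Parameters
    ----------
    axes : ndarray, shape (n_samples, 3)
        Acceleration in g for the x, y and z axes.
    sample_rate : float
        Sampling rate in Hz (default 100).
    subject_id : str
        Subject / recording identifier.
    start_clock_s : float
        Clock time of the first sample as seconds after midnight; used for
        hour-of-day false-positive reporting.
    """

    axes: np.ndarray
    sample_rate: float = 100.0
    subject_id: str = ""
    start_clock_s: float = 0.0

    def __post_init__(self) -> None:
        self.axes = np.asarray(self.axes, dtype=float)
        if self.axes.ndim != 2 or self.axes.shape[1] != 3:
            raise ValueError("axes must have shape (n_samples, 3)")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if self.axes.size:
            if not np.all(np.isfinite(self.axes)):
                raise ValueError("acceleration values must be finite")
            amax = float(np.abs(self.axes).max())
            if amax > SENSOR_RANGE_G:
                raise ValueError(
                    f"acceleration value {amax:g} g exceeds the +/-{SENSOR_RANGE_G:g} g sensor range"
                )
        if not (0.0 <= self.start_clock_s < 86400.0):
            raise ValueError("start_clock_s must lie in [0, 86400)")

    def __len__(self) -> int:
        return self.axes.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate

    @property
    def duration_h(self) -> float:
        return self.duration_s / 3600.0


@dataclass
class MagnitudeSeries:
    """Nonnegative acceleration-magnitude series in g."""

    values: np.ndarray
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if self.values.size and float(self.values.min()) < 0:
            raise ValueError("magnitude values must be nonnegative")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class WindowSpec:
    """Short-time analysis window: length, overlap and taper.

    Defaults reproduce the method's configuration: 100 samples (1 s at
    100 Hz), 50% overlap, Hamming taper.
    """

    length_samples: int = 100
    overlap_fraction: float = 0.5
    taper: str = "hamming"

    def __post_init__(self) -> None:
        if self.length_samples < 2:
            raise ValueError("length_samples must be >= 2")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.taper not in ("hamming", "rectangular"):
            raise ValueError("taper must be 'hamming' or 'rectangular'")

    @property
    def step_samples(self) -> int:
        step = int(round(self.length_samples * (1.0 - self.overlap_fraction)))
        return max(step, 1)

    def taper_coefficients(self) -> np.ndarray:
        n = self.length_samples
        if self.taper == "rectangular":
            return np.ones(n)
        # symmetric Hamming, 0.54 - 0.46 cos(2 pi n / (N - 1))
        return 0.54 - 0.46 * np.cos(2.0 * np.pi * np.arange(n) / (n - 1))


@dataclass
class Spectrum:
    """Magnitude spectrum on an integer frequency grid 0..f_max Hz."""

    magnitudes: np.ndarray
    f_max_hz: int = 50

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.magnitudes.shape != (self.f_max_hz + 1,):
            raise ValueError(
                f"expected {self.f_max_hz + 1} bins, got {self.magnitudes.shape}"
            )
        if not np.all(np.isfinite(self.magnitudes)):
            raise ValueError("magnitudes must be finite")
        if self.magnitudes.size and float(self.magnitudes.min()) < 0:
            raise ValueError("magnitudes must be nonnegative")

    @property
    def bins_hz(self) -> np.ndarray:
        return np.arange(self.f_max_hz + 1)


# ---------------------------------------------------------------------------
# CSV I/O
#
# Schema: optional '#'-prefixed metadata lines ('# subject_id: S1',
# '# start_clock_s: 27000'), then a header 'time_s,ax_g,ay_g,az_g' and one row
# per sample.  Sample rate is inferred from the time column and must be
# uniform within 1%.

_HEADER = "time_s,ax_g,ay_g,az_g"


def read_recording(path: str | Path, format: str = "csv") -> AcmRecording:
    """Read a 3-axis recording from CSV, validating schema and sensor range."""
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    meta: dict[str, str] = {}
    header = None
    data_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            if header is None:
                header = line
                if header.replace(" ", "") != _HEADER:
                    raise SchemaError(
                        f"{path}: expected header '{_HEADER}', got '{header}'"
                    )
                continue
            data_lines.append(line)

    if header is None:
        raise SchemaError(f"{path}: missing header line '{_HEADER}'")

    sample_rate = float(meta.get("sample_rate_hz", 0.0) or 0.0)
    if data_lines:
        try:
            table = np.loadtxt(
                io.StringIO("\n".join(data_lines)), delimiter=",", ndmin=2
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: malformed data row ({exc})") from exc
        if table.shape[1] != 4:
            raise SchemaError(f"{path}: expected 4 columns, got {table.shape[1]}")
        time_s, axes = table[:, 0], table[:, 1:]
        if len(time_s) >= 2:
            dt = np.diff(time_s)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise SchemaError(f"{path}: non-monotonic time column at row {row}")
            mean_dt = float(dt.mean())
            if np.any(np.abs(dt - mean_dt) > 0.01 * mean_dt):
                row = int(np.argmax(np.abs(dt - mean_dt) > 0.01 * mean_dt)) + 1
                raise SchemaError(
                    f"{path}: non-uniform sampling interval at row {row}"
                )
            inferred = 1.0 / mean_dt
            if sample_rate <= 0:
                sample_rate = inferred
            elif abs(inferred - sample_rate) > 0.01 * sample_rate:
                raise SchemaError(
                    f"{path}: time column implies {inferred:g} Hz, metadata says "
                    f"{sample_rate:g} Hz"
                )
        bad = np.abs(axes) > SENSOR_RANGE_G
        if bad.any():
            row = int(np.argmax(bad.any(axis=1)))
            raise SchemaError(
                f"{path}: value out of +/-{SENSOR_RANGE_G:g} g range at data row {row}"
            )
        if not np.all(np.isfinite(axes)):
            row = int(np.argmax(~np.isfinite(axes).all(axis=1)))
            raise SchemaError(f"{path}: non-finite value at data row {row}")
    else:
        axes = np.empty((0, 3))

    if sample_rate <= 0:
        sample_rate = 100.0
    return AcmRecording(
        axes=axes,
        sample_rate=sample_rate,
        subject_id=meta.get("subject_id", path.stem),
        start_clock_s=float(meta.get("start_clock_s", 0.0)),
    )


def write_recording(rec: AcmRecording, path: str | Path) -> None:
    """Write a recording to the CSV schema read by :func:`read_recording`."""
    path = Path(path)
    n = len(rec)
    t = np.arange(n) / rec.sample_rate
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# subject_id: {rec.subject_id}\n")
        fh.write(f"# start_clock_s: {rec.start_clock_s:g}\n")
        fh.write(f"# sample_rate_hz: {rec.sample_rate:g}\n")
        fh.write(_HEADER + "\n")
        np.savetxt(
            fh,
            np.column_stack([t, rec.axes]),
            delimiter=",",
            fmt=["%.3f", "%.5f", "%.5f", "%.5f"],
        )


# ---------------------------------------------------------------------------
# Preprocessing and windowing


def vector_magnitude(rec: AcmRecording) -> MagnitudeSeries:
    """Element-wise ``sqrt(x^2 + y^2 + z^2)`` of the three axes."""
    values = np.sqrt(np.einsum("ij,ij->i", rec.axes, rec.axes))
    return MagnitudeSeries(values=values, sample_rate=rec.sample_rate)


def window_start_indices(n_samples: int, spec: WindowSpec) -> np.ndarray:
    """Start sample of every complete analysis window.

    Windows begin at multiples of the hop (``N * (1 - overlap)``); a trailing
    stretch shorter than one full window is discarded.
    """
    n, step = spec.length_samples, spec.step_samples
    if n_samples < n:
        return np.empty(0, dtype=int)
    m = (n_samples - n) // step + 1
    return np.arange(m) * step


def segment_windows(series: MagnitudeSeries, spec: WindowSpec) -> np.ndarray:
    """All complete windows of the series, shape ``(n_windows, N)``."""
    starts = window_start_indices(len(series), spec)
    if starts.size == 0:
        return np.empty((0, spec.length_samples))
    view = sliding_window_view(series.values, spec.length_samples)
    return view[starts].copy()


def _bin_indices(spec: WindowSpec, sample_rate: float, f_max_hz: int) -> np.ndarray:
    """DFT bin index of each integer frequency 0..f_max Hz."""
    n = spec.length_samples
    if f_max_hz > sample_rate / 2:
        raise ValueError(
            f"f_max {f_max_hz} Hz exceeds the Nyquist frequency {sample_rate / 2:g} Hz"
        )
    idx = np.arange(f_max_hz + 1) * n / sample_rate
    rounded = np.rint(idx)
    if np.any(np.abs(idx - rounded) > 1e-9):
        raise ValueError(
            "integer-Hz frequency grid requires window length x (1 Hz) / sample_rate "
            f"to be integral (N={n}, fs={sample_rate:g})"
        )
    return rounded.astype(int)


def window_spectrum(
    window: np.ndarray,
    spec: WindowSpec,
    sample_rate: float = 100.0,
    f_max_hz: int = 50,
    mode: str = "magnitude",
) -> Spectrum:
    """Tapered DFT magnitude of one window at integer frequencies 0..f_max Hz."""
    window = np.asarray(window, dtype=float)
    if window.shape != (spec.length_samples,):
        raise ValueError(
            f"window has {window.shape} samples, spec requires {spec.length_samples}"
        )
    mags = window_spectra(window[None, :], spec, sample_rate, f_max_hz, mode)[0]
    return Spectrum(magnitudes=mags, f_max_hz=f_max_hz)


def window_spectra(
    windows: np.ndarray,
    spec: WindowSpec,
    sample_rate: float = 100.0,
    f_max_hz: int = 50,
    mode: str = "magnitude",
) -> np.ndarray:
    """Batch form of :func:`window_spectrum`; returns ``(n_windows, f_max+1)``.

    ``mode`` selects magnitude ``|X|`` (default) or power ``|X|^2`` spectra;
    the downstream templates and scores are defined on whichever is chosen.
    """
    if mode not in ("magnitude", "power"):
        raise ValueError("mode must be 'magnitude' or 'power'")
    windows = np.asarray(windows, dtype=float)
    tapered = windows * spec.taper_coefficients()
    full = np.abs(np.fft.rfft(tapered, axis=-1))
    mags = full[:, _bin_indices(spec, sample_rate, f_max_hz)]
    if mode == "power":
        mags = mags**2
    return mags


def iter_recordings(paths: Sequence[str | Path]) -> Iterator[AcmRecording]:
    for p in paths:
        yield read_recording(p)
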