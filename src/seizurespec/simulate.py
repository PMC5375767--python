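"""Seeded simulator of labeled wrist-accelerometer recordings.

The generator emulates the statistical structure the spectral detector relies
on, without claiming biomechanical realism:

* a ~1 g gravity baseline on the z axis with slow orientation drift;
* interictal movement as band-limited noise with most power below 0.8 Hz and
  a weaker component up to 4 Hz, modulated by an hourly activity profile;
* occasional high-amplitude quasi-sinusoidal 1–3 Hz *distractor* bouts
  (tooth-brushing-like rhythmic movement), placed preferentially in daytime
  hours — these are what trip an amplitude-based detector;
* generalized tonic-clonic seizures as amplitude-enveloped oscillations whose
  frequency declines linearly (default 9 Hz to 4 Hz) over the event, with a
  second harmonic, phase jitter and multiplicative amplitude jitter, giving
  the 4–25 Hz broadband ictal signature;
* additive white sensor noise on every axis.

All randomness flows from the single integer seed in :class:`SimConfig`;
identical configurations produce bit-identical recordings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .recording import SENSOR_RANGE_G, AcmRecording, write_recording
from .templates import SeizureAnnotation, write_annotation

__all__ = ["SimConfig", "simulate_recording", "simulate_cohort", "default_activity_profile"]


def default_activity_profile() -> tuple[float, ...]:
    """Hourly activity multipliers: quiet nights, active days."""
    profile = [0.15] * 24
    for h in range(8, 22):
        profile[h] = 1.0
    profile[7] = profile[22] = 0.5
    return tuple(profile)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated recording."""

    duration_h: float = 1.5
    sample_rate: float = 100.0
    n_seizures: int = 1
    seizure_duration_range_s: tuple[float, float] = (89.0, 256.0)
    clonic_freq_start_hz: float = 9.0
    clonic_freq_end_hz: float = 4.0
    seizure_amp_g: float = 2.0
    harmonic_ratio: float = 0.3
    interictal_amp_g: float = 0.3
    interictal_band_hz: float = 4.0
    dominant_band_hz: float = 0.8
    distractor_rate_per_h: float = 2.0
    distractor_freq_range_hz: tuple[float, float] = (1.0, 3.0)
    distractor_amp_g: float = 3.0
    distractor_duration_range_s: tuple[float, float] = (8.0, 20.0)
    sensor_noise_g: float = 0.005
    activity_profile: tuple[float, ...] = field(default_factory=default_activity_profile)
    start_clock_s: float = 8 * 3600.0
    subject_id: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_h <= 0 or self.sample_rate <= 0:
            raise ValueError("duration_h and sample_rate must be positive")
        if self.n_seizures < 0:
            raise ValueError("n_seizures must be >= 0")
        lo, hi = self.seizure_duration_range_s
        if not (0 < lo <= hi):
            raise ValueError("seizure_duration_range_s must be positive and ordered")
        nyq = self.sample_rate / 2
        for f in (
            self.clonic_freq_start_hz,
            self.clonic_freq_end_hz,
            self.interictal_band_hz,
            *self.distractor_freq_range_hz,
        ):
            if not (0 < f < nyq):
                raise ValueError("frequencies must lie below the Nyquist frequency")
        if min(
            self.seizure_amp_g,
            self.interictal_amp_g,
            self.distractor_amp_g,
        ) <= 0 or self.sensor_noise_g < 0:
            raise ValueError("amplitudes must be positive")
        if len(self.activity_profile) != 24:
            raise ValueError("activity_profile needs 24 hourly multipliers")


def _lowpass_noise(rng: np.random.Generator, n: int, fs: float, cutoff_hz: float) -> np.ndarray:
    """Unit-variance noise low-passed at ``cutoff_hz``."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    filtered = signal.sosfilt(sos, white)
    sd = filtered.std()
    return filtered / sd if sd > 0 else filtered


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    norm = np.linalg.norm(v)
    while norm < 1e-9:
        v = rng.standard_normal(3)
        norm = np.linalg.norm(v)
    return v / norm


def _activity_envelope(config: SimConfig, n: int) -> np.ndarray:
    """Per-sample activity multiplier, linear between hour midpoints."""
    fs = config.sample_rate
    t_clock = (config.start_clock_s + np.arange(n) / fs) % 86400.0
    hours = np.arange(-0.5, 25.5)  # midpoints in hours, wrapped
    profile = np.asarray(config.activity_profile)
    values = np.concatenate([[profile[23]], profile, [profile[0]]])
    return np.interp(t_clock / 3600.0, hours + 0.5, values)


def _place_intervals(
    rng: np.random.Generator,
    duration_s: float,
    lengths: list[float],
    forbidden: list[tuple[float, float]],
    edge_margin_s: float,
    max_tries: int = 200,
) -> list[tuple[float, float]]:
    """Place non-overlapping intervals avoiding the forbidden set."""
    placed: list[tuple[float, float]] = []
    for length in lengths:
        lo_max = duration_s - edge_margin_s - length
        if lo_max <= edge_margin_s:
            raise ValueError(
                f"cannot place a {length:.0f}-s interval in a "
                f"{duration_s:.0f}-s recording"
            )
        for _ in range(max_tries):
            onset = rng.uniform(edge_margin_s, lo_max)
            candidate = (onset, onset + length)
            busy = forbidden + placed
            if all(candidate[1] <= a or candidate[0] >= b for a, b in busy):
                placed.append(candidate)
                break
        else:
            raise ValueError("could not place intervals without overlap")
    return sorted(placed)


def _seizure_waveform(
    rng: np.random.Generator, config: SimConfig, n: int
) -> np.ndarray:
    """Clonic-phase oscillation: declining chirp with harmonic and jitter."""
    fs = config.sample_rate
    f_inst = np.linspace(config.clonic_freq_start_hz, config.clonic_freq_end_hz, n)
    f_inst = f_inst + 0.3 * _lowpass_noise(rng, n, fs, 0.5)  # frequency wander
    phase = 2.0 * np.pi * np.cumsum(f_inst) / fs
    phase = phase + 0.15 * _lowpass_noise(rng, n, fs, 1.0)  # phase jitter
    envelope = signal.windows.tukey(n, alpha=0.2)
    envelope = envelope * np.clip(1.0 + 0.3 * _lowpass_noise(rng, n, fs, 0.3), 0.2, None)
    wave = np.sin(phase) + config.harmonic_ratio * np.sin(2.0 * phase)
    return config.seizure_amp_g * envelope * wave


def simulate_recording(config: SimConfig) -> tuple[AcmRecording, SeizureAnnotation]:
    """Generate one labeled 3-axis recording under the configured conditions."""
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    n = int(round(config.duration_h * 3600.0 * fs))
    duration_s = n / fs
    axes = np.zeros((n, 3))

    # gravity on z with slow orientation drift
    t = np.arange(n) / fs
    drift_phase = rng.uniform(0, 2 * np.pi, size=2)
    axes[:, 2] += 1.0 + 0.04 * np.sin(2 * np.pi * 0.002 * t + drift_phase[0])
    axes[:, 0] += 0.05 * np.sin(2 * np.pi * 0.0013 * t + drift_phase[1])

    # interictal movement: dominant <0.8 Hz plus weaker component up to 4 Hz
    activity = _activity_envelope(config, n)
    for axis in range(3):
        slow = _lowpass_noise(rng, n, fs, config.dominant_band_hz)
        fast = _lowpass_noise(rng, n, fs, config.interictal_band_hz)
        axes[:, axis] += activity * config.interictal_amp_g * (slow + 0.2 * fast)

    # seizures
    durations = [
        rng.uniform(*config.seizure_duration_range_s) for _ in range(config.n_seizures)
    ]
    seizure_intervals = (
        _place_intervals(rng, duration_s, durations, [], edge_margin_s=120.0)
        if config.n_seizures
        else []
    )
    for onset, offset in seizure_intervals:
        lo, hi = int(round(onset * fs)), int(round(offset * fs))
        wave = _seizure_waveform(rng, config, hi - lo)
        direction = _random_unit_vector(rng)
        axes[lo:hi] += wave[:, None] * direction

    # distractor bouts, rate modulated by the activity profile
    distractors: list[tuple[float, float]] = []
    hour_edges = np.arange(0.0, duration_s + 3600.0, 3600.0)
    for h_lo in hour_edges[:-1]:
        h_hi = min(h_lo + 3600.0, duration_s)
        clock_hour = int(((config.start_clock_s + h_lo) % 86400.0) // 3600.0)
        expected = (
            config.distractor_rate_per_h
            * config.activity_profile[clock_hour]
            * (h_hi - h_lo)
            / 3600.0
        )
        for _ in range(rng.poisson(expected)):
            length = rng.uniform(*config.distractor_duration_range_s)
            try:
                (interval,) = _place_intervals(
                    rng,
                    duration_s,
                    [length],
                    seizure_intervals + distractors,
                    edge_margin_s=5.0,
                    max_tries=20,
                )
            except ValueError:
                continue
            distractors.append(interval)
            lo, hi = int(round(interval[0] * fs)), int(round(interval[1] * fs))
            m = hi - lo
            freq = rng.uniform(*config.distractor_freq_range_hz)
            amp = config.distractor_amp_g * rng.uniform(0.8, 1.2)
            envelope = signal.windows.tukey(m, alpha=0.3)
            burst = amp * envelope * np.sin(
                2 * np.pi * freq * np.arange(m) / fs + rng.uniform(0, 2 * np.pi)
            )
            axes[lo:hi] += burst[:, None] * _random_unit_vector(rng)

    # sensor noise
    if config.sensor_noise_g > 0:
        axes += config.sensor_noise_g * rng.standard_normal(axes.shape)

    if np.abs(axes).max(initial=0.0) > SENSOR_RANGE_G:
        warnings.warn(
            f"simulated acceleration exceeded +/-{SENSOR_RANGE_G:g} g and was clipped",
            stacklevel=2,
        )
        np.clip(axes, -SENSOR_RANGE_G, SENSOR_RANGE_G, out=axes)

    recording = AcmRecording(
        axes=axes,
        sample_rate=fs,
        subject_id=config.subject_id,
        start_clock_s=config.start_clock_s,
    )
    annotation = SeizureAnnotation(
        intervals=seizure_intervals, recording_id=config.subject_id
    )
    return recording, annotation


# ---------------------------------------------------------------------------
# Cohort generation

#: Start clocks cycled across cohort folds: mostly daytime admissions with a
#: few evening/night starts, so recordings sample the whole day.
_COHORT_START_HOURS = (8, 10, 13, 20, 2, 9, 15, 17, 22, 11)


def simulate_cohort(
    config: SimConfig, k: int = 10, out_dir: str | Path | None = None
) -> list[tuple[AcmRecording, SeizureAnnotation]]:
    """Generate ``k`` labeled recordings (one seizure each by default).

    Each fold gets its own child seed derived from ``config.seed`` and a start
    clock cycled over day and night hours.  When ``out_dir`` is given, the
    recordings, annotations and a fold manifest consumable by the ``evaluate``
    command are written there.
    """
    if k < 2:
        raise ValueError("a cohort needs at least 2 folds")
    rng = np.random.default_rng(config.seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=k)
    cohort = []
    manifest = {"folds": []}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for i in range(k):
        fold_config = replace(
            config,
            seed=int(child_seeds[i]),
            start_clock_s=_COHORT_START_HOURS[i % len(_COHORT_START_HOURS)] * 3600.0,
            subject_id=f"SIM{i + 1:02d}",
        )
        recording, annotation = simulate_recording(fold_config)
        cohort.append((recording, annotation))
        if out_path is not None:
            rec_file = out_path / f"fold{i + 1:02d}.csv"
            ann_file = out_path / f"fold{i + 1:02d}.json"
            write_recording(recording, rec_file)
            write_annotation(annotation, ann_file)
            manifest["folds"].append(
                {"recording": rec_file.name, "annotation": ann_file.name}
            )
    if out_path is not None:
        with open(out_path / "folds.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
    return cohort
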