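"""Run-wide configuration with the method's published defaults.

The defaults reproduce the detector's stated operating point: 1-s (100
sample) Hamming windows with 50% overlap, magnitude spectra to 50 Hz
including DC, a 10-score (5-s) trailing SCR average, and a 500-sample (5-s)
Stdev window hopped by 50 samples.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .recording import WindowSpec

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    window_n: int = 100
    overlap_fraction: float = 0.5
    taper: str = "hamming"
    f_max_hz: int = 50
    spectrum_mode: str = "magnitude"  # 'magnitude' | 'power'
    exclude_dc: bool = False
    smooth_k: int = 10
    stdev_n: int = 500
    stdev_step: int = 50
    eps_floor: float = 1e-12
    merge_gap_s: float = 30.0
    epoch_s: float = 5.0
    threshold_margin: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spectrum_mode not in ("magnitude", "power"):
            raise ValueError("spectrum_mode must be 'magnitude' or 'power'")
        if self.smooth_k < 1 or self.stdev_n < 2 or self.stdev_step < 1:
            raise ValueError("smooth_k >= 1, stdev_n >= 2, stdev_step >= 1 required")
        if self.epoch_s <= 0 or self.merge_gap_s < 0:
            raise ValueError("epoch_s must be > 0 and merge_gap_s >= 0")
        if not (0 < self.threshold_margin < 1):
            raise ValueError("threshold_margin must lie in (0, 1)")
        if self.eps_floor <= 0:
            raise ValueError("eps_floor must be positive")
        self.window_spec()  # validates window parameters

    def window_spec(self) -> WindowSpec:
        return WindowSpec(
            length_samples=self.window_n,
            overlap_fraction=self.overlap_fraction,
            taper=self.taper,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        doc = yaml.safe_load(text) or {}  # YAML is a superset of JSON
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(doc)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
        else:
            path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
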