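"""Run configuration with YAML round-trip.

Defaults follow the analysis conventions used throughout the package:
theta (4-7 Hz) and alpha (8-13 Hz) order-4 Butterworth bands, 60-s epochs,
3+3 CSP components, adaptation rate 0.1 per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features_classifier import ALPHA, THETA, BandSpec

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    bands: list[BandSpec] = field(default_factory=lambda: [THETA, ALPHA])
    epoch_length_s: float = 60.0
    method: str = "bfa"
    n_csp_per_end: int = 3
    lam: float = 0.1
    shrinkage: float | None = None  # None -> analytic (Ledoit-Wolf) coefficient
    zero_phase: bool = False
    fs: float = 200.0
    epochs_per_block: int | None = None  # None -> paradigm default durations
    seeds: list[int] = field(default_factory=lambda: [1])
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bands": [
                {
                    "name": b.name,
                    "low_hz": b.low_hz,
                    "high_hz": b.high_hz,
                    "order": b.order,
                    "design": b.design,
                }
                for b in self.bands
            ],
            "epoch_length_s": self.epoch_length_s,
            "method": self.method,
            "n_csp_per_end": self.n_csp_per_end,
            "lam": self.lam,
            "shrinkage": self.shrinkage,
            "zero_phase": self.zero_phase,
            "fs": self.fs,
            "epochs_per_block": self.epochs_per_block,
            "seeds": list(self.seeds),
            "paths": dict(self.paths),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        bands = [BandSpec(**b) for b in d.pop("bands", [])] or [THETA, ALPHA]
        return cls(bands=bands, **d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
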