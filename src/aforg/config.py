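"""Pipeline configuration.

Protocol constants (50 s analysis windows, 5 x 10 s SampEn sub-segments,
up to 5 windows per phase, >= 70 % PVI-completion eligibility) have fixed
defaults; everything else — sampling rates, entropy parameters, generator
physiology — is configurable and the resolved configuration is persisted
next to every pipeline output so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SampEnConfig:
    """Sample-entropy parameters: template length ``m`` and tolerance
    ``r`` as a fraction of the segment's own standard deviation."""

    m: int = 2
    r: float = 0.2

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError(f"SampEn m must be >= 1, got {self.m}")
        if not self.r > 0:
            raise ValueError(f"SampEn r must be > 0, got {self.r}")


@dataclass
class PipelineConfig:
    """Resolved settings for a full simulate -> entropy -> rri -> tables run."""

    fs: float = 1000.0              # Hz, both EGM and ECG
    window_s: float = 50.0          # analysis-window length
    subwindow_s: float = 10.0       # SampEn sub-segment length
    max_windows: int = 5            # windows per recording phase
    shen_bins: int = 64             # amplitude-histogram bins
    egm_sampen: SampEnConfig = field(default_factory=SampEnConfig)
    rri_sampen: SampEnConfig = field(default_factory=SampEnConfig)
    pvi_threshold: float = 0.70     # inclusive eligibility threshold
    rri_min_ms: float = 200.0       # interval plausibility band
    rri_max_ms: float = 3000.0
    seed: int = 0
    out_dir: str = "aforg_out"

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.window_s <= 0 or self.subwindow_s <= 0:
            raise ValueError("window lengths must be positive")
        n_sub = self.window_s / self.subwindow_s
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError(
                f"subwindow_s ({self.subwindow_s}) must divide "
                f"window_s ({self.window_s}) evenly"
            )
        if self.shen_bins < 2:
            raise ValueError("shen_bins must be >= 2")
        if not 0 <= self.pvi_threshold <= 1:
            raise ValueError("pvi_threshold must lie in [0, 1]")
        if self.rri_min_ms >= self.rri_max_ms:
            raise ValueError("rri_min_ms must be below rri_max_ms")
        self.egm_sampen.validate()
        self.rri_sampen.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("egm_sampen", "rri_sampen"):
            if key in d and isinstance(d[key], dict):
                d[key] = SampEnConfig(**d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        """Persist the resolved analysis configuration (the output
        location itself is omitted: the file lives inside it)."""
        d = self.to_dict()
        d.pop("out_dir")
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def digest(self) -> str:
        """Stable short hash of the analysis-relevant configuration
        (the output location does not affect results)."""
        d = self.to_dict()
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
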