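"""Analysis configuration: every window, cutoff and threshold in one place.

Defaults are the study conditions: 3 Hz / 4th-order low-pass, 5-min
z-score window, 0.5-s smoothing, 1-s extremum refinement, 30-s epochs and
AHI severity thresholds 5/15/30.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    cutoff_hz: float = 3.0
    filter_order: int = 4
    zscore_window_s: float = 300.0
    artifact_min_gap_s: float = 1.0
    smooth_window_s: float = 0.5
    refine_window_s: float = 1.0
    epoch_s: float = 30.0
    detach_window_s: float = 2.0
    detach_amp_frac: float = 0.02
    ahi_thresholds: tuple[float, ...] = (5.0, 15.0, 30.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ahi_thresholds" in data:
            data["ahi_thresholds"] = tuple(float(t) for t in data["ahi_thresholds"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["ahi_thresholds"] = list(self.ahi_thresholds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
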