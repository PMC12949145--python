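"""Pipeline configuration: one flat record of every tunable parameter.

Defaults follow the recording protocol and analysis conventions this
package implements (10 s median window, 0.5 Hz slow-wave and 1-5 Hz burst
bands, 40 s analysis windows, 0.95 mm electrode pitch, 30 Hz working rate);
parameters the protocol leaves open carry this package's documented
choices.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # preprocessing
    fs_out_hz: float = 30.0
    median_window_s: float = 10.0
    noise_factor: float = 3.0
    content_min: float = 3.0
    # detection
    detect_min_amp_mv: float = 0.2
    detect_k: float = 4.0
    detect_lowpass_hz: float = 0.5
    merge_s: float = 10.0
    max_spread_s: float = 45.0
    min_channels: int = 3
    window_s: float = 40.0
    # waveform measurement
    band_low_hz: float = 1.0
    band_high_hz: float = 5.0
    slow_cutoff_hz: float = 0.5
    ssa_window_slow_s: float = 2.0
    ssa_window_burst_s: float = 3.0
    otsu_bins: int = 256
    burst_min_rel_range: float = 1.0
    # propagation
    min_grad_s_per_mm: float = 1e-3
    sign_frac: float = 0.3
    per_column_direction: bool = False
    band_s: float = 2.0
    # statistics
    adjust: str = "tukey"
    # reproducibility
    seed: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        out = Path(path)
        out.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance logs."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
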