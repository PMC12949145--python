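"""On-disk formats for recordings, events and metrics.

A recording is stored as a TSV signal matrix (``time_s`` column followed by
one column per electrode channel) plus a JSON sidecar carrying the sampling
rate, electrode-grid geometry and animal/stage metadata.  Event tables and
metric tables are plain CSV.  All formats are human-inspectable and
language-neutral.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: The four stages of the rat oestrous cycle, in cycle order.
STAGES = ("pro-oestrus", "oestrus", "metoestrus", "dioestrus")

#: Decimal precision used when serialising signal samples.
SIGNAL_FMT = "%.6g"


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class IntegrityError(ValueError):
    """File contents are structurally valid but internally inconsistent."""


def _default_channel_map(n_rows: int, n_cols: int) -> tuple[tuple[int, int], ...]:
    """Row-major channel layout: channel = row * n_cols + col."""
    return tuple((r, c) for r in range(n_rows) for c in range(n_cols))


@dataclass(frozen=True)
class ElectrodeGrid:
    """Geometry of the taped electrode-array pair on the uterine horn.

    Two 8x4 flexible arrays taped end to end along the horn give the default
    16 rows x 4 columns at 0.95 mm pitch (~14.25 mm of horn covered).  Row
    index increases from the ovarian toward the cervical end; ``ovarian_row``
    says which end of the row axis is nearest the ovaries, so arrays applied
    in the reverse orientation can be described without re-ordering channels.

    ``channel_map[i]`` gives the (row, col) position of signal column ``i``
    and must be a bijection onto the full grid.
    """

    n_rows: int = 16
    n_cols: int = 4
    spacing_mm: float = 0.95
    ovarian_row: int = 0
    channel_map: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")
        if self.ovarian_row not in (0, self.n_rows - 1):
            raise ValueError("ovarian_row must be one end of the row axis")
        if self.channel_map is None:
            object.__setattr__(
                self, "channel_map", _default_channel_map(self.n_rows, self.n_cols)
            )
        cm = tuple(tuple(rc) for rc in self.channel_map)
        object.__setattr__(self, "channel_map", cm)
        expected = {(r, c) for r in range(self.n_rows) for c in range(self.n_cols)}
        if len(cm) != len(expected) or set(cm) != expected:
            raise ValueError("channel_map must be a bijection onto the grid")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def rowcol_of(self, channel: int) -> tuple[int, int]:
        return self.channel_map[channel]

    def channel_of(self, row: int, col: int) -> int:
        return self.channel_map.index((row, col))

    def positions_mm(self) -> np.ndarray:
        """(n_channels, 2) array of (x, y) positions in mm.

        x runs across the circumference (columns); y runs along the horn and
        increases from the ovarian toward the cervical end, so
        ovarian-to-cervical propagation has positive y-velocity.
        """
        pos = np.empty((self.n_channels, 2))
        for ch, (r, c) in enumerate(self.channel_map):
            y_steps = r if self.ovarian_row == 0 else (self.n_rows - 1 - r)
            pos[ch] = (c * self.spacing_mm, y_steps * self.spacing_mm)
        return pos

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "spacing_mm": self.spacing_mm,
            "ovarian_row": self.ovarian_row,
            "channel_map": [list(rc) for rc in self.channel_map],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElectrodeGrid":
        cm = d.get("channel_map")
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            spacing_mm=float(d["spacing_mm"]),
            ovarian_row=int(d.get("ovarian_row", 0)),
            channel_map=tuple(tuple(rc) for rc in cm) if cm is not None else None,
        )


@dataclass
class Recording:
    """A multichannel serosal recording with its geometry and metadata.

    ``signal`` is (n_samples, n_channels) in mV; columns follow the grid's
    channel order.  ``retained_channels`` lists the channels kept after
    screening (all channels until screening has run).
    """

    signal: np.ndarray
    fs_hz: float
    grid: ElectrodeGrid = field(default_factory=ElectrodeGrid)
    stage: str = "unknown"
    animal_id: str = ""
    retained_channels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (n_samples, n_channels) array")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if self.signal.shape[1] != self.grid.n_channels:
            raise IntegrityError(
                f"signal has {self.signal.shape[1]} channels but the grid "
                f"declares {self.grid.n_channels}"
            )
        if not np.isfinite(self.signal).all():
            raise IntegrityError("signal contains non-finite samples")
        if self.stage not in STAGES + ("unknown",):
            raise ValueError(f"unknown stage label {self.stage!r}")
        if self.retained_channels is None:
            self.retained_channels = tuple(range(self.grid.n_channels))
        else:
            self.retained_channels = tuple(int(c) for c in self.retained_channels)
            if any(c < 0 or c >= self.grid.n_channels for c in self.retained_channels):
                raise IntegrityError("retained_channels outside the channel range")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def with_signal(self, signal: np.ndarray) -> "Recording":
        return replace(self, signal=signal)


def _paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix == ".tsv":
        p = p.with_suffix("")
    return p.with_suffix(".tsv"), p.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> tuple[Path, Path]:
    """Write a recording as ``<path>.tsv`` plus ``<path>.json`` sidecar."""
    if rec.n_samples == 0:
        raise ValueError("refusing to write an empty recording")
    tsv, sidecar = _paths(path)
    cols = {"time_s": rec.times()}
    for ch in range(rec.grid.n_channels):
        cols[f"ch{ch:03d}"] = rec.signal[:, ch]
    pd.DataFrame(cols).to_csv(tsv, sep="\t", index=False, float_format=SIGNAL_FMT)
    meta = {
        "fs_hz": rec.fs_hz,
        "grid": rec.grid.to_dict(),
        "stage": rec.stage,
        "animal_id": rec.animal_id,
        "retained_channels": list(rec.retained_channels),
    }
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return tsv, sidecar


def read_recording(path: str | Path) -> Recording:
    """Read a TSV + JSON recording pair written by :func:`write_recording`."""
    tsv, sidecar = _paths(path)
    if not tsv.exists():
        raise FormatError(f"signal file not found: {tsv}")
    if not sidecar.exists():
        raise FormatError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    grid = ElectrodeGrid.from_dict(meta["grid"])
    frame = pd.read_csv(tsv, sep="\t")
    chan_cols = [c for c in frame.columns if c != "time_s"]
    if len(chan_cols) != grid.n_channels:
        raise IntegrityError(
            f"TSV has {len(chan_cols)} channel columns but the sidecar grid "
            f"declares {grid.n_channels}"
        )
    signal = frame[chan_cols].to_numpy(dtype=float)
    if not np.isfinite(signal).all():
        raise IntegrityError("signal contains non-finite samples")
    return Recording(
        signal=signal,
        fs_hz=float(meta["fs_hz"]),
        grid=grid,
        stage=meta.get("stage", "unknown"),
        animal_id=meta.get("animal_id", ""),
        retained_channels=tuple(meta.get("retained_channels", range(grid.n_channels))),
    )


def events_frame(events, measurements, fields=None) -> pd.DataFrame:
    """Assemble the per-(event, channel) analysis table.

    ``measurements`` maps (event_id, channel) to a burst/slow-wave
    measurement; ``fields`` optionally maps event_id to a velocity field.
    Rows are ordered by (event_id, channel) so output is deterministic.
    """
    rows = []
    for ev in sorted(events, key=lambda e: e.event_id):
        for ch in sorted(ev.marks):
            m = (measurements or {}).get((ev.event_id, ch))
            vf = (fields or {}).get(ev.event_id)
            vx = vy = math.nan
            if vf is not None and ch in vf.vectors:
                vx, vy = vf.vectors[ch]
            rows.append(
                {
                    "event_id": ev.event_id,
                    "channel": ch,
                    "activation_time_s": ev.marks[ch],
                    "slow_duration_s": m.slow_duration_s if m else math.nan,
                    "burst_present": bool(m.burst_present) if m else False,
                    "burst_duration_s": (
                        m.burst_duration_s
                        if (m and m.burst_present and m.burst_duration_s is not None)
                        else math.nan
                    ),
                    "vx_mm_s": vx,
                    "vy_mm_s": vy,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "channel",
            "activation_time_s",
            "slow_duration_s",
            "burst_present",
            "burst_duration_s",
            "vx_mm_s",
            "vy_mm_s",
        ],
    )


def write_events_table(events, measurements, path, fields=None) -> Path:
    """Write the events CSV; identical inputs produce byte-identical files."""
    out = Path(path)
    events_frame(events, measurements, fields).to_csv(
        out, index=False, float_format="%.6g", na_rep=""
    )
    return out
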