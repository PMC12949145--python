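"""End-to-end orchestration: preprocess -> detect -> measure -> map -> metrics."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .detect import Event, detect_events
from .io import Recording, read_recording, write_events_table
from .preprocess import detrend_recording, downsample_recording, screen_channels
from .propagation import DegenerateFieldError, VelocityField, estimate_velocity_field
from .stats import aggregate_by_stage, build_report, event_metrics, metric_rows
from .waveform import ComponentMeasurement, measure_event

log = logging.getLogger("uteromap")


@dataclass
class AnalysisResult:
    """Everything one recording contributes to the study."""

    recording: Recording
    events: list[Event]
    measurements: dict[tuple[int, int], ComponentMeasurement]
    fields: dict[int, VelocityField | None]
    metrics: dict = field(default_factory=dict)


def analyze_recording(rec: Recording, cfg: PipelineConfig | None = None) -> AnalysisResult:
    """Run the full single-recording analysis chain."""
    cfg = cfg or PipelineConfig()
    rec = downsample_recording(rec, cfg.fs_out_hz)
    rec = detrend_recording(rec, cfg.median_window_s)
    rec.retained_channels = screen_channels(rec, cfg.noise_factor, cfg.content_min)
    events = detect_events(
        rec,
        min_amp_mv=cfg.detect_min_amp_mv,
        max_spread_s=cfg.max_spread_s,
        min_channels=cfg.min_channels,
        width_s=cfg.window_s,
        k=cfg.detect_k,
        lowpass_hz=cfg.detect_lowpass_hz,
        merge_s=cfg.merge_s,
    )
    measurements: dict[tuple[int, int], ComponentMeasurement] = {}
    fields: dict[int, VelocityField | None] = {}
    for ev in events:
        for m in measure_event(
            ev,
            ssa_window_slow_s=cfg.ssa_window_slow_s,
            ssa_window_burst_s=cfg.ssa_window_burst_s,
            otsu_bins=cfg.otsu_bins,
            min_rel_range=cfg.burst_min_rel_range,
        ):
            measurements[(m.event_id, m.channel)] = m
        try:
            fields[ev.event_id] = estimate_velocity_field(
                ev, rec.grid, cfg.min_grad_s_per_mm
            )
        except DegenerateFieldError as exc:
            log.warning("event %d: no velocity field (%s)", ev.event_id, exc)
            fields[ev.event_id] = None
    metrics = event_metrics(events, measurements, fields, rec)
    log.info(
        "%s [%s]: %d/%d channels retained, %d events",
        rec.animal_id,
        rec.stage,
        len(rec.retained_channels),
        rec.grid.n_channels,
        len(events),
    )
    return AnalysisResult(rec, events, measurements, fields, metrics)


def run_pipeline(
    recordings: list[Recording | str | Path],
    out_dir: str | Path,
    cfg: PipelineConfig | None = None,
) -> Path:
    """Analyse a cohort of recordings and write all study artefacts.

    Emits per-recording events CSVs, a per-animal metrics CSV, the
    per-stage summary, the stage-comparison P-value report, and a
    provenance log.  A failure in one recording is logged and the rest of
    the cohort is still processed.
    """
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = []
    processed = []
    for item in recordings:
        rec = item if isinstance(item, Recording) else read_recording(item)
        try:
            res = analyze_recording(rec, cfg)
        except Exception as exc:  # keep going; one bad recording must not stop the cohort
            log.error("recording %s failed: %s", rec.animal_id, exc)
            continue
        write_events_table(
            res.events,
            res.measurements,
            out / f"events_{rec.animal_id or 'rec'}.csv",
            res.fields,
        )
        tables.append(metric_rows(rec.animal_id, rec.stage, res.metrics))
        processed.append(rec.animal_id)

    if tables:
        table = pd.concat(tables, ignore_index=True)
        table.to_csv(out / "metrics.csv", index=False, float_format="%.6g", na_rep="")
        aggregate_by_stage(table).to_csv(
            out / "stage_summary.csv", index=False, float_format="%.6g", na_rep=""
        )
        stages_present = table.dropna(subset=["value"])["stage"].nunique()
        if stages_present >= 2:
            build_report(table, adjust=cfg.adjust).to_csv(
                out / "stage_comparisons.csv", index=False, float_format="%.6g", na_rep=""
            )

    provenance = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "recordings": processed,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True) + "\n")
    return out
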