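"""Synthetic multichannel uterine recordings with exact ground truth.

The generator emulates the statistical structure of in vivo serosal
recordings from the rat uterine horn: rhythmic electrical events every
40-60 s, each a ~20 s biphasic slow-wave deflection optionally carrying a
1-5 Hz burst of ~10 s, propagating along the horn at ~0.5-1 mm/s in
stage-dependent direction mixtures.  Stage presets carry the per-stage
means and SDs of interval, durations, speed, burst prevalence and
direction mixture observed across the oestrous cycle, so the analysis
pipeline can be validated by parameter recovery against known truth.

Waveform conventions
--------------------
* Slow wave: one full sine cycle ``A sin(2 pi t / D)`` over its duration
  ``D`` -- a smooth biphasic pulse (depolarisation lobe, trough, recovery)
  whose maximum negative gradient sits exactly at ``D/2``.  The generator's
  nominal per-channel activation time is that steepest-descent instant,
  making ground truth directly comparable to the detector's output.
* Burst: a 3 Hz carrier (centre of the 1-5 Hz analysis band) under a Tukey
  envelope centred on the activation time.  The ground-truth burst duration
  is the envelope's full width at half maximum, which is the quantity a
  half-height threshold on the envelope trend recovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import ElectrodeGrid, Recording, STAGES

DIRECTION_CLASSES = (
    "ovarian_cervical",
    "cervical_ovarian",
    "other_colliding",
    "other_centre",
    "other_disorganised",
)

#: Shortest admissible inter-event interval (s); rejection-sampled below this.
MIN_INTERVAL_S = 5.0
#: Per-channel activation jitter (s) of disorganised events.
DISORGANISED_JITTER_S = 5.0
#: Tukey taper fraction of the burst envelope (short smooth ramps).
BURST_TAPER = 0.25


@dataclass
class StagePreset:
    """Generator parameters for one oestrous stage.

    Intervals, durations and speeds are normal means/SDs in seconds and
    mm/s; ``direction_mix`` gives probabilities over the five generated
    propagation patterns; artefact parameters feed :func:`add_artefacts`.
    Amplitudes (slow wave 1 mV, burst 0.4 mV, noise SD 0.05 mV) are free
    generator choices -- the recordings being emulated are reported only in
    normalised units.
    """

    stage: str
    interval_mean_s: float
    interval_sd_s: float
    slow_dur_mean_s: float = 19.9
    slow_dur_sd_s: float = 2.2
    burst_dur_mean_s: float = 10.2
    burst_dur_sd_s: float = 3.0
    burst_prevalence: float = 1.0
    speed_mean_mm_s: float = 0.57
    speed_sd_mm_s: float = 0.08
    direction_mix: dict[str, float] = field(
        default_factory=lambda: {"ovarian_cervical": 1.0}
    )
    noise_sd_mv: float = 0.05
    drift_amp_mv: float = 0.5
    resp_hz: float = 0.8
    heart_hz: float = 5.5
    resp_amp_mv: float = 0.1
    heart_amp_mv: float = 0.1
    slow_amp_mv: float = 1.0
    burst_amp_mv: float = 0.4
    burst_carrier_hz: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "interval_mean_s",
            "interval_sd_s",
            "slow_dur_mean_s",
            "slow_dur_sd_s",
            "burst_dur_mean_s",
            "burst_dur_sd_s",
            "speed_mean_mm_s",
            "speed_sd_mm_s",
            "noise_sd_mv",
            "drift_amp_mv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.burst_prevalence <= 1.0:
            raise ValueError("burst_prevalence must lie in [0, 1]")
        if self.slow_dur_mean_s <= self.burst_dur_mean_s:
            raise ValueError("mean slow-wave duration must exceed mean burst duration")
        unknown = set(self.direction_mix) - set(DIRECTION_CLASSES)
        if unknown:
            raise ValueError(f"unknown direction classes: {sorted(unknown)}")
        if any(p < 0 for p in self.direction_mix.values()):
            raise ValueError("direction_mix probabilities must be non-negative")
        if abs(sum(self.direction_mix.values()) - 1.0) > 1e-9:
            raise ValueError("direction_mix must sum to 1")


def _mix(oc: float, co: float, other: float) -> dict[str, float]:
    return {
        "ovarian_cervical": oc,
        "cervical_ovarian": co,
        "other_colliding": other / 3.0,
        "other_centre": other / 3.0,
        "other_disorganised": other / 3.0,
    }


# Per-stage observed values: inter-event interval, propagation speed, burst
# prevalence and direction mixture; slow-wave (19.9 +/- 2.2 s) and burst
# (10.2 +/- 3.0 s) durations did not differ between stages and share one set
# of defaults.
_PRESETS: dict[str, dict] = {
    "pro-oestrus": dict(
        interval_mean_s=49.1,
        interval_sd_s=3.7,
        speed_mean_mm_s=0.57,
        speed_sd_mm_s=0.07,
        burst_prevalence=0.72,
        direction_mix=_mix(0.40, 0.20, 0.40),
    ),
    "oestrus": dict(
        interval_mean_s=46.5,
        interval_sd_s=5.0,
        speed_mean_mm_s=0.82,
        speed_sd_mm_s=0.09,
        burst_prevalence=0.92,
        direction_mix=_mix(0.92, 0.0, 0.08),
    ),
    "metoestrus": dict(
        interval_mean_s=60.5,
        interval_sd_s=2.6,
        speed_mean_mm_s=0.93,
        speed_sd_mm_s=0.23,
        burst_prevalence=0.82,
        direction_mix=_mix(0.52, 0.08, 0.40),
    ),
    "dioestrus": dict(
        interval_mean_s=40.2,
        interval_sd_s=5.6,
        speed_mean_mm_s=0.57,
        speed_sd_mm_s=0.08,
        burst_prevalence=0.70,
        direction_mix=_mix(0.44, 0.0, 0.56),
    ),
}


def make_stage_preset(stage: str, **overrides) -> StagePreset:
    """Build the preset for one oestrous stage; keyword overrides allowed."""
    key = stage.strip().lower()
    if key not in _PRESETS:
        raise ValueError(f"unknown oestrous stage {stage!r}; expected one of {STAGES}")
    params = dict(_PRESETS[key])
    params.update(overrides)
    return StagePreset(stage=key, **params)


@dataclass
class EventTruth:
    """Ground truth for one generated event."""

    onset_s: float
    direction: str
    speed_mm_s: float
    activation_s: np.ndarray  # per-channel activation times (s)
    slow_duration_s: float
    burst_present: bool
    burst_duration_s: float | None  # envelope FWHM, None when no burst


@dataclass
class GroundTruth:
    """Everything the generator knows about a recording."""

    events: list[EventTruth]
    dead_channels: tuple[int, ...] = ()
    fs_hz: float = 30.0

    @property
    def n_events(self) -> int:
        return len(self.events)

    def reference_times(self) -> np.ndarray:
        """Median per-event activation times, the event reference clock."""
        return np.array([np.median(ev.activation_s) for ev in self.events])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ev in enumerate(self.events):
            for ch, t in enumerate(ev.activation_s):
                rows.append(
                    {
                        "event_id": i,
                        "channel": ch,
                        "onset_s": ev.onset_s,
                        "direction": ev.direction,
                        "speed_mm_s": ev.speed_mm_s,
                        "activation_time_s": t,
                        "slow_duration_s": ev.slow_duration_s,
                        "burst_present": ev.burst_present,
                        "burst_duration_s": ev.burst_duration_s,
                        "dead": ch in self.dead_channels,
                    }
                )
        return pd.DataFrame(rows)

    def write_csv(self, path) -> Path:
        out = Path(path)
        self.to_frame().to_csv(out, index=False, float_format="%.6g", na_rep="")
        return out


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    """Normal draw rejection-sampled above ``low``; degenerate when sd = 0."""
    if sd == 0:
        if mean <= low:
            raise ValueError("degenerate truncated normal entirely below bound")
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > low:
            return x
    raise ValueError("truncated normal rejection sampling failed")


def slow_wave_template(n: int, fs_hz: float, duration_s: float, amp_mv: float) -> np.ndarray:
    """Biphasic slow-wave pulse: one sine cycle over ``duration_s``."""
    t = np.arange(n) / fs_hz
    return amp_mv * np.sin(2.0 * np.pi * t / duration_s)


def burst_waveform(
    fwhm_s: float,
    fs_hz: float,
    amp_mv: float,
    carrier_hz: float,
    taper: float = BURST_TAPER,
) -> np.ndarray:
    """Amplitude-modulated burst whose envelope FWHM equals ``fwhm_s``."""
    support_s = fwhm_s / (1.0 - taper / 2.0)
    n = max(int(round(support_s * fs_hz)), 3)
    env = sps.windows.tukey(n, alpha=taper)
    t = np.arange(n) / fs_hz - 0.5 * (n - 1) / fs_hz
    return amp_mv * env * np.sin(2.0 * np.pi * carrier_hz * t)


def activation_delays(
    direction: str,
    speed_mm_s: float,
    grid: ElectrodeGrid,
    rng: np.random.Generator | None = None,
    jitter_sd_s: float = 0.0,
) -> np.ndarray:
    """Per-channel activation delays (s) relative to event onset.

    Plane waves run from the ovarian end (``ovarian_cervical``), the
    cervical end (``cervical_ovarian``), both ends meeting mid-horn
    (``other_colliding``) or diverge from the middle (``other_centre``);
    ``other_disorganised`` events have independent per-channel jitter with
    no coherent gradient.
    """
    y = grid.positions_mm()[:, 1]
    length = y.max()
    if direction == "ovarian_cervical":
        delays = y / speed_mm_s
    elif direction == "cervical_ovarian":
        delays = (length - y) / speed_mm_s
    elif direction == "other_colliding":
        delays = np.minimum(y, length - y) / speed_mm_s
    elif direction == "other_centre":
        delays = np.abs(y - length / 2.0) / speed_mm_s
    elif direction == "other_disorganised":
        if rng is None:
            raise ValueError("disorganised delays need a random generator")
        delays = rng.normal(0.0, DISORGANISED_JITTER_S, size=grid.n_channels)
        delays -= delays.min()
    else:
        raise ValueError(f"unknown direction class {direction!r}")
    if jitter_sd_s > 0:
        if rng is None:
            raise ValueError("jittered delays need a random generator")
        delays = delays + rng.normal(0.0, jitter_sd_s, size=grid.n_channels)
    return delays


def _max_burst_fwhm(slow_duration_s: float) -> float:
    # Burst envelope support must stay inside 90% of the slow wave.
    return 0.9 * slow_duration_s * (1.0 - BURST_TAPER / 2.0)


def _draw_event(
    rng: np.random.Generator, preset: StagePreset, onset_s: float, grid: ElectrodeGrid
) -> EventTruth:
    classes = list(DIRECTION_CLASSES)
    probs = np.array([preset.direction_mix.get(c, 0.0) for c in classes])
    direction = classes[rng.choice(len(classes), p=probs / probs.sum())]
    speed = _trunc_normal(rng, preset.speed_mean_mm_s, preset.speed_sd_mm_s, 0.05)
    slow_dur = _trunc_normal(rng, preset.slow_dur_mean_s, preset.slow_dur_sd_s, 5.0)
    burst_present = bool(rng.random() < preset.burst_prevalence)
    burst_dur = None
    if burst_present:
        burst_dur = _trunc_normal(rng, preset.burst_dur_mean_s, preset.burst_dur_sd_s, 2.0)
        burst_dur = min(burst_dur, _max_burst_fwhm(slow_dur))
    delays = activation_delays(direction, speed, grid, rng)
    return EventTruth(
        onset_s=onset_s,
        direction=direction,
        speed_mm_s=speed,
        activation_s=onset_s + delays,
        slow_duration_s=slow_dur,
        burst_present=burst_present,
        burst_duration_s=burst_dur,
    )


def _add_at(out: np.ndarray, start: int, wave: np.ndarray) -> None:
    """Add ``wave`` into ``out`` starting at ``start``, clipping at edges."""
    n = out.shape[0]
    i0, i1 = max(start, 0), min(start + len(wave), n)
    if i1 > i0:
        out[i0:i1] += wave[i0 - start : i1 - start]


def simulate_recording(
    preset: StagePreset,
    duration_s: float,
    grid: ElectrodeGrid | None = None,
    seed: int = 0,
    fs_hz: float = 30.0,
    n_dead: int = 0,
) -> tuple[Recording, GroundTruth]:
    """Generate a clean (artefact-free) recording plus its ground truth.

    Event onsets follow truncated-normal inter-event intervals; each event
    places the same slow-wave (and optional burst) waveform on every
    channel, shifted by its propagation delay.  Pass the result through
    :func:`add_artefacts` for drift, respiration/heart lines, white noise
    and dead channels.  Generation is at 30 Hz by default; a higher rate
    exists to exercise the downsampler.
    """
    if duration_s < 60:
        raise ValueError("duration_s must be at least 60 s to hold one event")
    grid = grid or ElectrodeGrid()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    signal = np.zeros((n, grid.n_channels))

    onsets = []
    t = 0.5 * _trunc_normal(rng, preset.interval_mean_s, preset.interval_sd_s, MIN_INTERVAL_S)
    while t <= duration_s - 10.0:
        onsets.append(t)
        t += _trunc_normal(rng, preset.interval_mean_s, preset.interval_sd_s, MIN_INTERVAL_S)
    if not onsets:
        raise ValueError("recording too short to hold one event at this interval")

    events = []
    for onset in onsets:
        ev = _draw_event(rng, preset, onset, grid)
        n_slow = max(int(round(ev.slow_duration_s * fs_hz)), 3)
        slow = slow_wave_template(n_slow, fs_hz, ev.slow_duration_s, preset.slow_amp_mv)
        burst = None
        if ev.burst_present:
            burst = burst_waveform(
                ev.burst_duration_s, fs_hz, preset.burst_amp_mv, preset.burst_carrier_hz
            )
        for ch in range(grid.n_channels):
            act = ev.activation_s[ch]
            start = int(round((act - ev.slow_duration_s / 2.0) * fs_hz))
            _add_at(signal[:, ch], start, slow)
            if burst is not None:
                _add_at(signal[:, ch], int(round(act * fs_hz)) - len(burst) // 2, burst)
        events.append(ev)

    dead = tuple(sorted(rng.choice(grid.n_channels, size=n_dead, replace=False))) if n_dead else ()
    rec = Recording(
        signal=signal,
        fs_hz=fs_hz,
        grid=grid,
        stage=preset.stage if preset.stage in STAGES else "unknown",
        animal_id=f"sim-{seed}",
    )
    return rec, GroundTruth(events=events, dead_channels=dead, fs_hz=fs_hz)


def add_artefacts(
    rec: Recording,
    preset: StagePreset,
    seed: int = 0,
    dead_channels: tuple[int, ...] = (),
) -> Recording:
    """Contaminate a clean recording with the artefacts the pipeline removes.

    Adds per-channel baseline drift (low-passed random walk below 0.05 Hz,
    RMS ``drift_amp_mv``), sinusoidal respiration and heart components with
    random per-channel phase, and white noise; declared dead channels are
    replaced by pure noise (poor-contact electrodes).
    """
    rng = np.random.default_rng(seed)
    n, n_ch = rec.signal.shape
    out = rec.signal.copy()
    t = rec.times()

    if preset.drift_amp_mv > 0:
        sos = sps.butter(2, 0.05, btype="lowpass", fs=rec.fs_hz, output="sos")
        for ch in range(n_ch):
            walk = np.cumsum(rng.standard_normal(n))
            drift = sps.sosfiltfilt(sos, walk - walk.mean())
            rms = np.sqrt(np.mean(drift**2))
            if rms > 0:
                out[:, ch] += preset.drift_amp_mv * drift / rms
    if preset.resp_amp_mv > 0:
        for ch in range(n_ch):
            out[:, ch] += preset.resp_amp_mv * np.sin(
                2 * np.pi * preset.resp_hz * t + rng.uniform(0, 2 * np.pi)
            )
    if preset.heart_amp_mv > 0:
        for ch in range(n_ch):
            out[:, ch] += preset.heart_amp_mv * np.sin(
                2 * np.pi * preset.heart_hz * t + rng.uniform(0, 2 * np.pi)
            )
    if preset.noise_sd_mv > 0:
        out += rng.normal(0.0, preset.noise_sd_mv, size=out.shape)
    for ch in dead_channels:
        out[:, ch] = rng.normal(0.0, max(preset.noise_sd_mv, 1e-12), size=n)
    return rec.with_signal(out)


def event_window(
    preset: StagePreset,
    rng: np.random.Generator,
    with_burst: bool | None = None,
    fs_hz: float = 30.0,
    width_s: float = 40.0,
) -> tuple[np.ndarray, dict]:
    """One synthetic single-channel analysis window centred on activation.

    Draws slow-wave/burst durations from the preset, centres the event's
    activation (steepest descent) at the window midpoint and adds white
    noise.  ``with_burst`` forces burst presence; by default it is drawn
    from the preset's prevalence.  Returns the window and its truth.
    """
    n = int(round(width_s * fs_hz))
    x = np.zeros(n)
    slow_dur = _trunc_normal(rng, preset.slow_dur_mean_s, preset.slow_dur_sd_s, 5.0)
    slow_dur = min(slow_dur, width_s - 4.0)  # keep the pulse inside the window
    burst = bool(rng.random() < preset.burst_prevalence) if with_burst is None else with_burst
    burst_dur = None
    centre = n // 2

    n_slow = max(int(round(slow_dur * fs_hz)), 3)
    _add_at(x, centre - n_slow // 2, slow_wave_template(n_slow, fs_hz, slow_dur, preset.slow_amp_mv))
    if burst:
        burst_dur = _trunc_normal(rng, preset.burst_dur_mean_s, preset.burst_dur_sd_s, 2.0)
        burst_dur = min(burst_dur, _max_burst_fwhm(slow_dur))
        bw = burst_waveform(burst_dur, fs_hz, preset.burst_amp_mv, preset.burst_carrier_hz)
        _add_at(x, centre - len(bw) // 2, bw)
    if preset.noise_sd_mv > 0:
        x += rng.normal(0.0, preset.noise_sd_mv, size=n)
    truth = {
        "slow_duration_s": slow_dur,
        "burst_present": burst,
        "burst_duration_s": burst_dur,
        "t_act_s": centre / fs_hz,
    }
    return x, truth
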