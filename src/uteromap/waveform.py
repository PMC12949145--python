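"""Burst/slow-wave separation and duration measurement.

Each 40 s event window is split by frequency: a 1-5 Hz band-pass isolates
the burst (fast oscillatory activity riding on the event) and a 0.5 Hz
low-pass isolates the slow wave (the tissue-level deflection).  Durations
are then measured on smooth trends extracted with singular spectrum
analysis (SSA):

* burst -- SSA trend of the rectified band-passed signal, min-max
  normalised and binarised with an Otsu threshold; the burst duration is
  the length of the supra-threshold segment containing the trend peak
  nearest the activation time, and a window with no such segment carries
  no burst;
* slow wave -- SSA trend of the low-passed signal; the duration runs from
  the last zero-gradient instant before the trend peak nearest activation
  (event initiation) to the second zero-gradient instant after it (the
  first is the event trough, the second the return to baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from skimage.filters import threshold_otsu

from .detect import Event, Window

#: Normalised-gradient magnitude treated as zero by the plateau rule,
#: calibrated so stationary points of closed-form pulses land within one
#: sample period of their analytic positions (see docs/methods.md).
ZERO_GRAD_EPS = 2.5e-3
#: Minimum run length (samples) of near-zero gradient to count as a plateau.
ZERO_GRAD_MIN_RUN = 3


@dataclass
class ComponentMeasurement:
    """Durations of the two frequency components of one event window."""

    event_id: int
    channel: int
    slow_duration_s: float | None
    burst_present: bool
    burst_duration_s: float | None
    diagnostic: str = ""


def _check_fs(fs_hz: float, edge_hz: float) -> None:
    if edge_hz >= fs_hz / 2:
        raise ValueError(
            f"sampling rate {fs_hz} Hz too low for a {edge_hz} Hz filter edge"
        )


def extract_burst_component(
    window: np.ndarray, fs_hz: float, low_hz: float = 1.0, high_hz: float = 5.0
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (1-5 Hz by default)."""
    _check_fs(fs_hz, high_hz)
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=fs_hz, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(window, dtype=float))


def extract_slow_component(
    window: np.ndarray, fs_hz: float, cutoff_hz: float = 0.5
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass (0.5 Hz by default)."""
    _check_fs(fs_hz, cutoff_hz)
    sos = sps.butter(4, cutoff_hz, btype="lowpass", fs=fs_hz, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(window, dtype=float))


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def ssa_trend(
    series: np.ndarray,
    window_len: int,
    n_components: int = 1,
    normalise: bool = True,
) -> np.ndarray:
    """Singular-spectrum-analysis trend of a 1-D series.

    Embeds the series in an ``window_len x K`` trajectory matrix, keeps the
    leading ``n_components`` of its SVD and reconstructs by diagonal
    averaging.  With ``normalise`` the trend is min-max scaled to [0, 1];
    a constant input returns all zeros (normalisation guard).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if not 2 <= window_len <= n // 2:
        raise ValueError("window_len must lie in [2, len(series) // 2]")
    if np.ptp(x) == 0:
        return np.zeros(n)
    L = window_len
    K = n - L + 1
    traj = np.lib.stride_tricks.sliding_window_view(x, L).T  # L x K
    u, s, vt = np.linalg.svd(traj, full_matrices=False)
    r = min(n_components, s.size)
    recon = (u[:, :r] * s[:r]) @ vt[:r]
    trend = np.zeros(n)
    counts = np.zeros(n)
    for i in range(L):
        trend[i : i + K] += recon[i]
        counts[i : i + K] += 1.0
    trend /= counts
    return _minmax(trend) if normalise else trend


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold of a 1-D series: maximises between-class variance
    over an ``nbins``-bin histogram."""
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size < 2 or np.ptp(vals) == 0:
        raise ValueError("otsu_threshold needs at least two distinct values")
    return float(threshold_otsu(vals, nbins=nbins))


def _zero_gradient_intervals(
    trend: np.ndarray,
    eps: float = ZERO_GRAD_EPS,
    min_run: int = ZERO_GRAD_MIN_RUN,
) -> list[tuple[int, int]]:
    """Stationary features of a normalised trend as (start, end) index pairs.

    Two kinds are found and merged: sign changes of the first difference
    (local extrema, single-sample intervals) and plateaus where the
    absolute difference stays below ``eps`` for at least ``min_run``
    consecutive steps (flat shoulders a pure sign-change rule misses).
    """
    d = np.diff(trend)
    intervals: list[tuple[int, int]] = []

    small = np.abs(d) < eps
    if small.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([False], small, [False])).astype(int)))
        for run_start, run_stop in zip(edges[::2], edges[1::2]):
            if run_stop - run_start >= min_run:
                intervals.append((int(run_start), int(run_stop)))

    big = ~small
    for i in range(d.size - 1):
        if big[i] and big[i + 1] and d[i] * d[i + 1] < 0:
            intervals.append((i + 1, i + 1))

    intervals.sort()
    merged: list[tuple[int, int]] = []
    for iv in intervals:
        if merged and iv[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], iv[1]))
        else:
            merged.append(iv)
    return merged


def _nearest_peak(trend: np.ndarray, centre: int) -> int | None:
    """Index of the local trend maximum nearest ``centre`` (earlier on ties)."""
    peaks, _ = sps.find_peaks(trend)
    if peaks.size == 0:
        return None
    dist = np.abs(peaks - centre)
    return int(peaks[np.argmin(dist)])  # argmin takes the first = earlier peak


def _window_array(window: Window | np.ndarray, fs_hz: float | None, t_act_s: float | None):
    if isinstance(window, Window):
        x = window.samples
        fs = window.fs_hz
        centre = window.centre_index
    else:
        x = np.asarray(window, dtype=float)
        if fs_hz is None:
            raise ValueError("fs_hz required when window is a bare array")
        fs = fs_hz
        centre = int(round(t_act_s * fs)) if t_act_s is not None else x.size // 2
    return x, fs, min(max(centre, 0), x.size - 1)


def measure_burst(
    window: Window | np.ndarray,
    fs_hz: float | None = None,
    t_act_s: float | None = None,
    ssa_window_s: float = 3.0,
    n_components: int = 1,
    otsu_bins: int = 256,
    min_rel_range: float = 1.0,
) -> tuple[bool, float | None]:
    """Detect a burst in one window and measure its duration.

    Pipeline: band-pass, rectify, SSA trend, min-max normalise, Otsu
    binarise; the burst duration is the supra-threshold segment containing
    the trend peak nearest the activation time.  If the trend's excursion
    is small relative to its median level (no significant or prolonged
    variation of the band-passed magnitude), or the nearest peak falls
    below threshold, the window carries no burst.
    """
    x, fs, centre = _window_array(window, fs_hz, t_act_s)
    band = extract_burst_component(x, fs)
    env = np.abs(band)
    L = max(2, min(int(round(ssa_window_s * fs)), env.size // 2))
    raw = ssa_trend(env, L, n_components, normalise=False)
    med = np.median(raw)
    if np.ptp(raw) < min_rel_range * max(med, 1e-12):
        return False, None
    trend = _minmax(raw)
    try:
        theta = otsu_threshold(trend, otsu_bins)
    except ValueError:
        return False, None
    peak = _nearest_peak(trend, centre)
    if peak is None or trend[peak] <= theta:
        return False, None
    above = trend > theta
    i0 = peak
    while i0 > 0 and above[i0 - 1]:
        i0 -= 1
    i1 = peak
    while i1 < above.size - 1 and above[i1 + 1]:
        i1 += 1
    return True, (i1 - i0 + 1) / fs


def measure_slow_wave(
    window: Window | np.ndarray,
    fs_hz: float | None = None,
    t_act_s: float | None = None,
    ssa_window_s: float = 2.0,
    n_components: int = 2,
) -> tuple[float | None, str]:
    """Measure the slow-wave duration of one window.

    Pipeline: low-pass, SSA trend, locate the trend peak nearest the
    activation time; the initiation is the nearest zero-gradient instant
    before the peak, and scanning forward the first zero-gradient instant
    is the event trough and the second the return to baseline.  Duration =
    return - initiation.  Returns ``(None, diagnostic)`` when the window
    lacks the required landmarks (e.g. a flat window).
    """
    x, fs, centre = _window_array(window, fs_hz, t_act_s)
    slow = extract_slow_component(x, fs)
    L = max(2, min(int(round(ssa_window_s * fs)), slow.size // 2))
    trend = ssa_trend(slow, L, n_components)
    if np.ptp(trend) == 0:
        return None, "flat window"
    peak = _nearest_peak(trend, centre)
    if peak is None:
        return None, "no trend peak"
    intervals = _zero_gradient_intervals(trend)
    before = [iv for iv in intervals if iv[1] <= peak - 2]
    after = [iv for iv in intervals if iv[0] >= peak + 2]
    if not before:
        return None, "no zero-gradient instant before the peak"
    if len(after) < 2:
        return None, "fewer than two zero-gradient instants after the peak"
    # The instant of a pre-peak plateau nearest the peak is its end; the
    # return instant of a post-peak plateau is where it begins.
    initiation = before[-1][1]
    baseline_return = after[1][0]
    return (baseline_return - initiation) / fs, ""


def measure_event(
    event: Event,
    ssa_window_slow_s: float = 2.0,
    ssa_window_burst_s: float = 3.0,
    otsu_bins: int = 256,
    min_rel_range: float = 1.0,
) -> list[ComponentMeasurement]:
    """Measure both components on every windowed channel of an event."""
    out = []
    for ch in sorted(event.windows):
        win = event.windows[ch]
        slow_dur, diag = measure_slow_wave(win, ssa_window_s=ssa_window_slow_s)
        present, burst_dur = measure_burst(
            win,
            ssa_window_s=ssa_window_burst_s,
            otsu_bins=otsu_bins,
            min_rel_range=min_rel_range,
        )
        out.append(
            ComponentMeasurement(
                event_id=event.event_id,
                channel=ch,
                slow_duration_s=slow_dur,
                burst_present=present,
                burst_duration_s=burst_dur,
                diagnostic=diag,
            )
        )
    return out
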