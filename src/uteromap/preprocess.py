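"""Signal conditioning: baseline removal, rate conversion, channel screening.

The conditioning chain mirrors standard serosal-EMG practice: recordings
acquired at 512 Hz are down-sampled to 30 Hz, baseline drift is estimated
with a 10 s moving median and subtracted, and channels with poor contact or
excessive noise are dropped before event detection.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io import IntegrityError, Recording


def remove_baseline(signal: np.ndarray, fs_hz: float, window_s: float = 10.0) -> np.ndarray:
    """Subtract the centred moving-median baseline estimate.

    The window is truncated (shrunk) at the recording edges so the output
    has the same length as the input.  Even-length windows use the lower
    median (element ``(w - 1) // 2`` of the sorted window), a fixed
    convention so results are reproducible across implementations.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("remove_baseline expects a 1-D signal")
    n = x.size
    if n == 0:
        raise ValueError("empty signal")
    w = int(round(window_s * fs_hz))
    if w < 3:
        raise ValueError("median window must span at least 3 samples")
    w = min(w, n)
    left = (w - 1) // 2  # samples before the centre
    right = w // 2  # samples after the centre
    k = (w - 1) // 2  # lower-median rank

    med = np.empty(n)
    if n >= w:
        wins = np.lib.stride_tricks.sliding_window_view(x, w)
        med[left : n - right] = np.partition(wins, k, axis=1)[:, k]
    for i in list(range(min(left, n))) + list(range(max(n - right, 0), n)):
        sub = x[max(0, i - left) : min(n, i + right + 1)]
        m = sub.size
        med[i] = np.partition(sub, (m - 1) // 2)[(m - 1) // 2]
    return x - med


def detrend_recording(rec: Recording, window_s: float = 10.0) -> Recording:
    """Apply :func:`remove_baseline` to every channel."""
    out = np.empty_like(rec.signal)
    for ch in range(rec.signal.shape[1]):
        out[:, ch] = remove_baseline(rec.signal[:, ch], rec.fs_hz, window_s)
    return rec.with_signal(out)


def downsample(signal: np.ndarray, fs_in: float = 512.0, fs_out: float = 30.0) -> np.ndarray:
    """Anti-aliased rational resampling from ``fs_in`` to ``fs_out``.

    Polyphase FIR resampling with an explicit anti-alias design: the
    passband extends to ~93% of the output Nyquist frequency and the
    stopband starts at Nyquist (attenuation > 50 dB), so e.g. a 14 Hz
    component survives a 512 -> 30 Hz conversion while 20 Hz is removed.
    Works on 1-D signals or (n_samples, n_channels) matrices.
    """
    if fs_out >= fs_in:
        raise ValueError("fs_out must be below fs_in")
    frac = Fraction(int(round(fs_out * 1_000_000)), int(round(fs_in * 1_000_000)))
    up, down = frac.numerator, frac.denominator
    f_ny = fs_out / 2.0
    transition_hz = f_ny / 15.0  # 93% of Nyquist passband edge
    fs_up = fs_in * up  # the polyphase filter runs at the upsampled rate
    numtaps = int(np.ceil(3.3 * fs_up / transition_hz)) | 1  # Hamming window rule
    h = sps.firwin(numtaps, f_ny - transition_hz / 2.0, fs=fs_up)
    return sps.resample_poly(np.asarray(signal, dtype=float), up, down, window=h, axis=0)


def downsample_recording(rec: Recording, fs_out: float = 30.0) -> Recording:
    if rec.fs_hz == fs_out:
        return rec
    out = downsample(rec.signal, rec.fs_hz, fs_out)
    new = rec.with_signal(out)
    new.fs_hz = fs_out
    return new


def screen_channels(
    rec: Recording,
    noise_factor: float = 3.0,
    content_min: float = 3.0,
    low_band_hz: float = 0.5,
    high_band_hz: float = 5.0,
) -> tuple[int, ...]:
    """Automated replacement for visual channel screening.

    A channel is rejected when its high-band (> 5 Hz) RMS exceeds
    ``noise_factor`` times the cross-channel median (noisy/motion-artefact
    electrodes), or when it shows no event content: for a poor-contact
    electrode recording only broadband noise, the slow-wave-band RMS
    (< 0.5 Hz) matches the level a flat spectrum predicts from the
    high-band RMS, whereas a live channel carries an order of magnitude
    more.  The content ratio (slow-band RMS over its flat-spectrum
    prediction) must reach ``content_min``; the ratio is scale-free, so
    screening is insensitive to amplitude calibration.  Expects a
    detrended recording.
    """
    x = rec.signal
    n, n_ch = x.shape
    nyq = rec.fs_hz / 2.0
    sos_hi = sps.butter(4, high_band_hz, btype="highpass", fs=rec.fs_hz, output="sos")
    sos_lo = sps.butter(4, low_band_hz, btype="lowpass", fs=rec.fs_hz, output="sos")
    rms_hi = np.sqrt(np.mean(sps.sosfiltfilt(sos_hi, x, axis=0) ** 2, axis=0))
    rms_lo = np.sqrt(np.mean(sps.sosfiltfilt(sos_lo, x, axis=0) ** 2, axis=0))
    med_rms = np.median(rms_hi)
    noisy = rms_hi > noise_factor * med_rms if med_rms > 0 else np.zeros(n_ch, bool)

    # flat-spectrum prediction of the low-band RMS from the high-band RMS
    band_scale = np.sqrt(low_band_hz / (nyq - high_band_hz))
    with np.errstate(divide="ignore", invalid="ignore"):
        content = np.where(rms_hi > 0, rms_lo / (band_scale * rms_hi), 0.0)
    dead = content < content_min

    retained = tuple(int(c) for c in np.flatnonzero(~(noisy | dead)))
    if not retained:
        raise IntegrityError(
            "channel screening rejected every channel "
            f"(high-band RMS median {med_rms:.3g} mV; check noise_factor/content_min)"
        )
    return retained


def preprocess_recording(
    rec: Recording,
    fs_out: float = 30.0,
    window_s: float = 10.0,
    noise_factor: float = 3.0,
    content_min: float = 3.0,
) -> Recording:
    """Full conditioning chain: downsample, detrend, screen channels."""
    rec = downsample_recording(rec, fs_out)
    rec = detrend_recording(rec, window_s)
    rec.retained_channels = screen_channels(rec, noise_factor, content_min)
    return rec
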