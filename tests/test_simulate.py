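"""Generator: stage presets, event placement, artefacts, ground truth."""

import numpy as np
import pytest
from scipy import signal as sps

from uteromap.io import ElectrodeGrid
from uteromap.simulate import (
    activation_delays,
    add_artefacts,
    event_window,
    make_stage_preset,
    simulate_recording,
)


@pytest.mark.parametrize(
    "stage, interval, speed, prevalence",
    [
        ("pro-oestrus", 49.1, 0.57, 0.72),
        ("oestrus", 46.5, 0.82, 0.92),
        ("metoestrus", 60.5, 0.93, 0.82),
        ("dioestrus", 40.2, 0.57, 0.70),
    ],
)
def test_stage_presets_carry_observed_values(stage, interval, speed, prevalence):
    p = make_stage_preset(stage)
    assert p.interval_mean_s == interval
    assert p.speed_mean_mm_s == speed
    assert p.burst_prevalence == prevalence
    assert p.slow_dur_mean_s == 19.9 and p.burst_dur_mean_s == 10.2


def test_direction_mixtures_match_observed_percentages():
    oe = make_stage_preset("oestrus").direction_mix
    assert oe["ovarian_cervical"] == 0.92
    assert oe["cervical_ovarian"] == 0.0
    pro = make_stage_preset("pro-oestrus").direction_mix
    assert pro["ovarian_cervical"] == 0.40
    assert pro["cervical_ovarian"] == 0.20
    met = make_stage_preset("metoestrus").direction_mix
    assert met["cervical_ovarian"] == 0.08
    di = make_stage_preset("dioestrus").direction_mix
    other = sum(v for k, v in di.items() if k.startswith("other"))
    assert other == pytest.approx(0.56)
    for stage in ("pro-oestrus", "oestrus", "metoestrus", "dioestrus"):
        assert sum(make_stage_preset(stage).direction_mix.values()) == pytest.approx(1.0)


def test_unknown_stage_rejected():
    with pytest.raises(ValueError):
        make_stage_preset("luteal")


def test_fixed_interval_without_spread_yields_six_events(grid):
    preset = make_stage_preset("oestrus", interval_mean_s=50.0, interval_sd_s=0.0)
    _, truth = simulate_recording(preset, 300.0, grid, seed=0)
    assert truth.n_events == 6  # 300 s / 50 s


def test_same_seed_is_bit_identical(grid):
    preset = make_stage_preset("dioestrus")
    rec_a, truth_a = simulate_recording(preset, 120.0, grid, seed=7)
    rec_b, truth_b = simulate_recording(preset, 120.0, grid, seed=7)
    assert np.array_equal(rec_a.signal, rec_b.signal)
    assert truth_a.dead_channels == truth_b.dead_channels
    for ea, eb in zip(truth_a.events, truth_b.events):
        assert np.array_equal(ea.activation_s, eb.activation_s)
        assert (ea.direction, ea.speed_mm_s) == (eb.direction, eb.speed_mm_s)


def test_zero_prevalence_leaves_burst_band_empty(grid):
    preset = make_stage_preset("oestrus", burst_prevalence=0.0, noise_sd_mv=0.0)
    rec, truth = simulate_recording(preset, 300.0, grid, seed=3)
    assert not any(ev.burst_present for ev in truth.events)
    sos = sps.butter(4, [1.0, 5.0], btype="bandpass", fs=30.0, output="sos")
    band_rms = np.sqrt(np.mean(sps.sosfiltfilt(sos, rec.signal[:, 0]) ** 2))
    total_rms = np.sqrt(np.mean(rec.signal[:, 0] ** 2))
    assert band_rms < 0.05 * total_rms


def test_plane_wave_delays_linear_in_row_position(grid):
    delays = activation_delays("ovarian_cervical", 0.5, grid)
    y = grid.positions_mm()[:, 1]
    np.testing.assert_allclose(delays, y / 0.5, rtol=0, atol=1e-12)
    # slope along the row axis = spacing / speed
    r0, r1 = grid.channel_of(0, 0), grid.channel_of(1, 0)
    assert delays[r1] - delays[r0] == pytest.approx(0.95 / 0.5)


def test_interval_and_burst_sampling_converge_to_preset(grid):
    small = ElectrodeGrid(n_rows=4, n_cols=2)
    preset = make_stage_preset("dioestrus")
    intervals, bursts, n_events = [], 0, 0
    for seed in range(8):
        _, truth = simulate_recording(preset, 1200.0, small, seed=seed)
        refs = np.sort([ev.onset_s for ev in truth.events])
        intervals.extend(np.diff(refs))
        bursts += sum(ev.burst_present for ev in truth.events)
        n_events += truth.n_events
    intervals = np.asarray(intervals)
    assert intervals.size >= 200
    assert np.all(intervals > 5.0)  # truncation floor
    se = preset.interval_sd_s / np.sqrt(intervals.size)
    assert abs(intervals.mean() - preset.interval_mean_s) < 3 * se
    p = preset.burst_prevalence
    se_p = np.sqrt(p * (1 - p) / n_events)
    assert abs(bursts / n_events - p) < 3 * se_p


def test_ground_truth_burst_shorter_than_slow_wave(grid):
    _, truth = simulate_recording(make_stage_preset("oestrus"), 600.0, grid, seed=5)
    for ev in truth.events:
        if ev.burst_present:
            assert ev.burst_duration_s < ev.slow_duration_s


def test_artefacts_identity_when_amplitudes_zero(grid):
    preset = make_stage_preset(
        "oestrus", noise_sd_mv=0.0, drift_amp_mv=0.0, resp_amp_mv=0.0, heart_amp_mv=0.0
    )
    rec, _ = simulate_recording(preset, 120.0, grid, seed=1)
    out = add_artefacts(rec, preset, seed=2)
    np.testing.assert_array_equal(out.signal, rec.signal)


def test_artefact_power_is_drift_plus_spectral_lines(grid):
    preset = make_stage_preset("oestrus", noise_sd_mv=0.0)
    rec, _ = simulate_recording(preset, 300.0, grid, seed=1)
    out = add_artefacts(rec, preset, seed=2)
    diff = out.signal[:, 0] - rec.signal[:, 0]
    f, pxx = sps.periodogram(diff, fs=30.0)
    drift = pxx[f < 0.1].sum()
    lines = pxx[np.abs(f - preset.resp_hz) < 0.05].sum() + pxx[np.abs(f - preset.heart_hz) < 0.05].sum()
    assert (drift + lines) / pxx.sum() > 0.95


def test_dead_channels_uncorrelated_with_events(grid):
    preset = make_stage_preset("oestrus")
    rec, truth = simulate_recording(preset, 300.0, grid, seed=9, n_dead=8)
    out = add_artefacts(rec, preset, seed=10, dead_channels=truth.dead_channels)
    assert len(truth.dead_channels) == 8
    live = [c for c in range(grid.n_channels) if c not in truth.dead_channels][0]
    for ch in truth.dead_channels:
        r = np.corrcoef(out.signal[:, ch], rec.signal[:, live])[0, 1]
        assert abs(r) < 0.2


def test_event_window_centres_activation_and_reports_truth(rng):
    win, info = event_window(make_stage_preset("oestrus"), rng, with_burst=True)
    assert win.shape == (1200,)
    assert info["t_act_s"] == pytest.approx(20.0)
    assert info["burst_present"] and info["burst_duration_s"] < info["slow_duration_s"]


def test_too_short_recording_rejected(grid):
    with pytest.raises(ValueError):
        simulate_recording(make_stage_preset("oestrus"), 30.0, grid, seed=0)
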