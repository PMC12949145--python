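"""Velocity fields, direction classification, isochronal maps."""

import numpy as np
import pytest

from uteromap.detect import Event
from uteromap.evaluation import direction_study
from uteromap.io import ElectrodeGrid
from uteromap.propagation import (
    DegenerateFieldError,
    VelocityField,
    classify_direction,
    estimate_velocity_field,
    isochronal_map,
    plot_isochronal_map,
)
from uteromap.simulate import activation_delays


def _plane_event(grid, direction, speed, t0=100.0, rng=None, jitter=0.0):
    delays = activation_delays(direction, speed, grid, rng, jitter)
    return Event(0, {ch: t0 + d for ch, d in enumerate(delays)})


@pytest.mark.parametrize("speed", [0.1, 0.5, 1.0, 5.0])
@pytest.mark.parametrize("direction", ["ovarian_cervical", "cervical_ovarian"])
def test_plane_wave_speed_exact_on_every_channel(grid, speed, direction):
    field = estimate_velocity_field(_plane_event(grid, direction, speed), grid)
    speeds = np.array(list(field.speeds.values()))
    assert speeds.size == grid.n_channels
    np.testing.assert_allclose(speeds, speed, rtol=0.01)
    assert field.direction == direction


def test_plane_wave_velocity_components(grid):
    # T = row * 0.95 / 0.5 with perfect synchrony across columns
    field = estimate_velocity_field(_plane_event(grid, "ovarian_cervical", 0.5), grid)
    for vx, vy in field.vectors.values():
        assert vx == pytest.approx(0.0, abs=1e-9)
        assert vy == pytest.approx(0.5, abs=1e-9)
    assert field.mean_speed_mm_s == pytest.approx(0.5, rel=1e-9)


def test_simultaneous_activation_is_degenerate(grid):
    with pytest.raises(DegenerateFieldError):
        estimate_velocity_field(Event(0, {ch: 50.0 for ch in range(64)}), grid)


def test_too_few_channels_rejected(grid):
    with pytest.raises(DegenerateFieldError):
        estimate_velocity_field(Event(0, {0: 1.0, 1: 2.0}), grid)


def test_jittered_plane_wave_speed_within_ten_percent(grid):
    rng = np.random.default_rng(5)
    est = [
        estimate_velocity_field(
            _plane_event(grid, "ovarian_cervical", 0.93, rng=rng, jitter=0.2), grid
        ).mean_speed_mm_s
        for _ in range(20)
    ]
    assert abs(np.mean(est) - 0.93) < 0.093


def test_speed_invariant_under_time_translation(grid):
    a = estimate_velocity_field(_plane_event(grid, "ovarian_cervical", 0.7, t0=10.0), grid)
    b = estimate_velocity_field(_plane_event(grid, "ovarian_cervical", 0.7, t0=210.0), grid)
    assert a.mean_speed_mm_s == pytest.approx(b.mean_speed_mm_s, rel=1e-12)
    assert list(a.speeds.values()) == pytest.approx(list(b.speeds.values()))


def _field_from_vy(grid, vy_by_channel):
    vectors = {ch: (0.0, vy) for ch, vy in vy_by_channel.items()}
    cols = {}
    for ch, vy in vy_by_channel.items():
        cols.setdefault(grid.rowcol_of(ch)[1], []).append(vy)
    col_means = np.full(grid.n_cols, np.nan)
    for c, vals in cols.items():
        col_means[c] = np.mean(vals)
    return VelocityField(0, vectors, {ch: abs(v) for ch, v in vy_by_channel.items()},
                         1.0, col_means)


def test_all_positive_column_means_is_ovarian_cervical(grid):
    field = _field_from_vy(grid, {ch: 0.4 + 0.1 * (ch % 2) for ch in range(64)})
    assert classify_direction(field, grid) == "ovarian_cervical"


def test_all_negative_column_means_is_cervical_ovarian(grid):
    field = _field_from_vy(grid, {ch: -0.4 - 0.1 * (ch % 2) for ch in range(64)})
    assert classify_direction(field, grid) == "cervical_ovarian"


def test_thirty_percent_opposing_components_is_other(grid):
    # 20 of 60 channel y-components (33%) oppose the mean; column means stay
    # positive, yet the event is "other" by the sign-fraction rule.
    vy = {}
    for ch in range(60):
        vy[ch] = -0.2 if ch % 3 == 0 else 0.8
    field = _field_from_vy(grid, vy)
    assert all(np.nanmean(field.column_mean_vy) > 0 for _ in [0])
    assert classify_direction(field, grid) == "other"


def test_direction_mixture_recovery_matches_preset(grid):
    study = direction_study("pro-oestrus", n_events=100, seed=3)
    mix = {"ovarian_cervical": 0.40, "cervical_ovarian": 0.20}
    for cls, p in mix.items():
        assert abs(study.classified_pct(cls) / 100 - p) < 0.06 + 2 * np.sqrt(p * (1 - p) / 100)
    other = study.classified_pct("other") / 100
    assert abs(other - 0.40) < 0.06 + 2 * np.sqrt(0.4 * 0.6 / 100)


def test_isochronal_bands_monotone_for_ovarian_origin(grid):
    event = _plane_event(grid, "ovarian_cervical", 0.5)
    bands = isochronal_map(event, grid, band_s=2.0)
    col0 = bands[:, 0].compressed()
    assert np.all(np.diff(col0) >= 0)
    assert bands[0, 0] == 0


def test_colliding_event_latest_band_in_interior(grid):
    event = _plane_event(grid, "other_colliding", 0.5)
    bands = isochronal_map(event, grid, band_s=2.0)
    latest_rows = np.where(bands == bands.max())[0]
    assert np.all((latest_rows > 0) & (latest_rows < grid.n_rows - 1))


def test_band_recomputable_from_stored_activation_times(grid):
    event = _plane_event(grid, "ovarian_cervical", 0.5)
    bands = isochronal_map(event, grid, band_s=2.0)
    t0 = min(event.marks.values())
    for ch, t in event.marks.items():
        r, c = grid.rowcol_of(ch)
        assert bands[r, c] == np.floor((t - t0) / 2.0)


def test_isochronal_map_masks_absent_channels_and_plots(grid, tmp_path):
    marks = {ch: 100 + 0.5 * grid.rowcol_of(ch)[0] for ch in range(0, 64, 2)}
    event = Event(3, marks)
    bands = isochronal_map(event, grid)
    assert bands.mask.sum() == 32
    out = tmp_path / "map.png"
    plot_isochronal_map(event, grid, path=out)
    assert out.exists() and out.stat().st_size > 0
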