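"""Velocity-field estimation, direction classification and isochronal maps.

Per-channel conduction velocities are derived from the spatial gradient of
the activation-time surface T(x, y) on the electrode grid: a wavefront
moving at speed ``s`` along direction ``u`` gives ``grad T = u / s``, so
``v = grad T / |grad T|^2`` and ``speed = 1 / |grad T|``.  The gradient at
each electrode comes from a least-squares plane fit of T over the 3x3
neighbourhood's available channels -- a smoothed finite-difference scheme
that is exact for plane waves everywhere on the grid, including edges, and
averages out activation-time jitter elsewhere.

The direction rule follows the column-mean convention: an event is
ovarian-cervical if the mean y-velocity of every grid column is positive,
cervical-ovarian if all are negative, and "other" for mixed signs or when
at least 30% of per-channel y-components oppose the overall mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import Event
from .io import ElectrodeGrid


class DegenerateFieldError(ValueError):
    """The activation-time surface carries no usable spatial gradient."""


@dataclass
class VelocityField:
    """Per-channel velocity vectors and the event's direction class."""

    event_id: int
    vectors: dict[int, tuple[float, float]]  # channel -> (vx, vy) mm/s
    speeds: dict[int, float]  # channel -> speed mm/s
    mean_speed_mm_s: float
    column_mean_vy: np.ndarray  # one value per grid column (NaN if empty)
    direction: str = "other"


def _activation_grid(event: Event, grid: ElectrodeGrid) -> np.ndarray:
    T = np.full((grid.n_rows, grid.n_cols), np.nan)
    for ch, t in event.marks.items():
        r, c = grid.rowcol_of(ch)
        T[r, c] = t
    return T


def estimate_velocity_field(
    event: Event,
    grid: ElectrodeGrid,
    min_grad_s_per_mm: float = 1e-3,
    neighbourhood: int = 1,
) -> VelocityField:
    """Estimate the per-channel velocity field of one event.

    Channels whose neighbourhood spans fewer than two distinct positions on
    either grid axis, or whose fitted gradient magnitude falls below
    ``min_grad_s_per_mm`` (near-synchronous activation, which would imply
    unbounded speed), receive no estimate.  The event's mean speed is the
    arithmetic mean of the per-channel speeds.
    """
    if len(event.marks) < 3:
        raise DegenerateFieldError("velocity estimation needs marks on >= 3 channels")
    T = _activation_grid(event, grid)
    rows_spanned = np.unique([grid.rowcol_of(ch)[0] for ch in event.marks])
    if rows_spanned.size < 2:
        raise DegenerateFieldError("velocity estimation needs marks spanning >= 2 rows")

    pos = grid.positions_mm()
    xy = {grid.rowcol_of(ch): pos[ch] for ch in range(grid.n_channels)}
    vectors: dict[int, tuple[float, float]] = {}
    speeds: dict[int, float] = {}
    h = neighbourhood
    for ch in sorted(event.marks):
        r0, c0 = grid.rowcol_of(ch)
        pts = []
        for r in range(max(0, r0 - h), min(grid.n_rows, r0 + h + 1)):
            for c in range(max(0, c0 - h), min(grid.n_cols, c0 + h + 1)):
                if np.isfinite(T[r, c]):
                    x, y = xy[(r, c)]
                    pts.append((x, y, T[r, c]))
        if len(pts) < 3:
            continue
        arr = np.array(pts)
        if np.unique(arr[:, 0]).size < 2 or np.unique(arr[:, 1]).size < 2:
            continue  # cannot resolve one of the gradient components
        A = np.column_stack([np.ones(len(arr)), arr[:, 0], arr[:, 1]])
        coef, *_ = np.linalg.lstsq(A, arr[:, 2], rcond=None)
        g = coef[1:3]  # (dT/dx, dT/dy) in s/mm
        gnorm = float(np.hypot(*g))
        if gnorm < min_grad_s_per_mm:
            continue
        vectors[ch] = (g[0] / gnorm**2, g[1] / gnorm**2)
        speeds[ch] = 1.0 / gnorm
    if not vectors:
        raise DegenerateFieldError(
            "all activation-time gradients degenerate (synchronous activation?)"
        )

    col_means = np.full(grid.n_cols, np.nan)
    by_col: dict[int, list[float]] = {}
    for ch, (_, vy) in vectors.items():
        by_col.setdefault(grid.rowcol_of(ch)[1], []).append(vy)
    for c, vals in by_col.items():
        col_means[c] = float(np.mean(vals))

    field = VelocityField(
        event_id=event.event_id,
        vectors=vectors,
        speeds=speeds,
        mean_speed_mm_s=float(np.mean(list(speeds.values()))),
        column_mean_vy=col_means,
    )
    field.direction = classify_direction(field, grid)
    return field


def classify_direction(
    field: VelocityField,
    grid: ElectrodeGrid | None = None,
    sign_frac: float = 0.3,
    per_column: bool = False,
) -> str:
    """Classify an event's propagation direction from its velocity field.

    All column-mean y-velocities positive -> ``ovarian_cervical``; all
    negative -> ``cervical_ovarian``; mixed signs -> ``other``.  An event is
    also ``other`` when at least ``sign_frac`` of the per-channel
    y-components oppose the sign of the mean y-component -- globally across
    the event by default, or within any single column with ``per_column``.
    """
    vy = np.array([v[1] for v in field.vectors.values()])
    if vy.size == 0:
        raise ValueError("velocity field carries no y-components")
    col_means = field.column_mean_vy[np.isfinite(field.column_mean_vy)]
    if col_means.size == 0:
        raise ValueError("no column-mean y-velocities available")

    if per_column and grid is not None:
        by_col: dict[int, list[float]] = {}
        for ch, (_, v) in field.vectors.items():
            by_col.setdefault(grid.rowcol_of(ch)[1], []).append(v)
        for vals in by_col.values():
            arr = np.array(vals)
            m = arr.mean()
            if m != 0 and np.mean(arr * m < 0) >= sign_frac:
                return "other"
    else:
        mean_vy = vy.mean()
        if mean_vy != 0 and np.mean(vy * mean_vy < 0) >= sign_frac:
            return "other"

    if np.all(col_means > 0):
        return "ovarian_cervical"
    if np.all(col_means < 0):
        return "cervical_ovarian"
    return "other"


def isochronal_map(event: Event, grid: ElectrodeGrid, band_s: float = 2.0) -> np.ma.MaskedArray:
    """Banded activation-time image on the grid.

    Each electrode's activation time is quantised into bands of ``band_s``
    seconds counted from the event's earliest activation; channels without
    a mark are masked.
    """
    T = _activation_grid(event, grid)
    t0 = np.nanmin(T)
    bands = np.floor((T - t0) / band_s)
    return np.ma.masked_invalid(bands)


def plot_isochronal_map(
    event: Event,
    grid: ElectrodeGrid,
    band_s: float = 2.0,
    path=None,
    ax=None,
):
    """Render the isochronal activation map (early red, late blue)."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    bands = isochronal_map(event, grid, band_s)
    if ax is None:
        fig, ax = plt.subplots(figsize=(3, 6))
    else:
        fig = ax.figure
    im = ax.imshow(bands, cmap="RdYlBu", origin="upper", aspect="equal")
    ax.set_xlabel("column")
    ax.set_ylabel("row (ovarian end at top)" if grid.ovarian_row == 0 else "row")
    ax.set_title(f"event {event.event_id}")
    fig.colorbar(im, ax=ax, label=f"activation band ({band_s} s)")
    if path is not None:
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return fig
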