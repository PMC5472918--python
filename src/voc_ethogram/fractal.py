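"""Box-counting fractal dimension of movement tracks.

The number N(r) of grid cells of side r (grid anchored at the arena origin)
containing at least one recorded position scales as N(r) ~ r^-D for a
self-similar track; D is estimated as the least-squares slope of log N(r)
against log(1/r).  A topological line gives D ~ 1, a track that fills the
two-dimensional arena evenly gives D ~ 2.

The default box sizes form a dyadic sequence from half the arena height down
to 0.5 mm; the floor sits well above the 0.1-mm movement-resolution threshold
so tracker noise is not counted as structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import Arena, TrackSet

#: Smallest default box size (mm).
MIN_BOX_MM = 0.5


@dataclass
class FractalEstimate:
    """Box sizes (descending), occupied-box counts, fitted dimension and fit quality."""

    box_sizes: np.ndarray
    counts: np.ndarray
    dimension: float
    fit_r2: float
    degenerate: bool = False
    truncated: bool = False


def default_box_sizes(arena: Arena | None = None) -> np.ndarray:
    """Dyadic sequence from height/2 down to :data:`MIN_BOX_MM` (descending)."""
    arena = arena if arena is not None else Arena()
    sizes = []
    r = arena.height / 2.0
    while r >= MIN_BOX_MM:
        sizes.append(r)
        r /= 2.0
    return np.asarray(sizes)


def box_count(points: np.ndarray, r: float, arena: Arena | None = None) -> int:
    """Number of cells of the grid of side ``r`` (anchored at the arena origin)
    that contain at least one point."""
    arena = arena if arena is not None else Arena()
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("box_count needs at least one point")
    if r <= 0:
        raise ValueError("box size must be positive")
    nx = max(1, int(np.ceil(arena.width / r)))
    ny = max(1, int(np.ceil(arena.height / r)))
    ix = np.minimum((points[:, 0] // r).astype(np.int64), nx - 1)
    iy = np.minimum((points[:, 1] // r).astype(np.int64), ny - 1)
    return int(np.unique(ix * ny + iy).size)


def estimate_dimension(
    points: np.ndarray,
    box_sizes: np.ndarray | None = None,
    arena: Arena | None = None,
) -> FractalEstimate:
    """Fit D as the slope of log N(r) versus log(1/r) over all supplied scales.

    Requires at least 4 box sizes spanning at least 2 octaves.  When every
    count is equal (e.g. a single repeated point) the estimate is flagged
    degenerate with D = 0.
    """
    arena = arena if arena is not None else Arena()
    sizes = np.sort(
        np.asarray(box_sizes if box_sizes is not None else default_box_sizes(arena))
    )[::-1].astype(float)
    if len(sizes) < 4:
        raise ValueError("need at least 4 box sizes")
    if sizes[0] / sizes[-1] < 4.0:
        raise ValueError("box sizes must span at least 2 octaves")
    counts = np.array([box_count(points, r, arena) for r in sizes])
    if np.all(counts == counts[0]):
        return FractalEstimate(sizes, counts, 0.0, 1.0, degenerate=True)
    x = np.log(1.0 / sizes)
    y = np.log(counts.astype(float))
    slope, _ = np.polyfit(x, y, 1)
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return FractalEstimate(sizes, counts, float(slope), r2)


def track_dimensions(
    trackset: TrackSet,
    window: float = 1800.0,
    box_sizes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-track, per-window dimension estimates.

    Windows tile the track without overlap (default 30 min).  A track shorter
    than one window produces a single estimate flagged ``truncated``.
    """
    if not trackset.tracks:
        return pd.DataFrame(
            columns=[
                "individual_id", "strain", "treatment", "session",
                "window", "dimension", "fit_r2", "n_points", "truncated",
            ]
        )
    dt = trackset.dt
    n_win = window / dt
    if abs(n_win - round(n_win)) > 1e-9 or n_win < 1:
        raise ValueError("window must be a positive multiple of dt")
    n_win = int(round(n_win))
    rows = []
    for t in trackset:
        n = t.n_positions
        if n <= n_win:
            chunks = [(0, t.positions, True)]
        else:
            chunks = [
                (k, t.positions[k * n_win : (k + 1) * n_win + 1], False)
                for k in range(n // n_win)
            ]
        for k, pts, truncated in chunks:
            est = estimate_dimension(pts, box_sizes, trackset.arena)
            rows.append(
                {
                    "individual_id": t.individual_id,
                    "strain": t.strain,
                    "treatment": t.treatment,
                    "session": t.session,
                    "window": k,
                    "dimension": est.dimension,
                    "fit_r2": est.fit_r2,
                    "n_points": len(pts),
                    "truncated": truncated or est.truncated,
                }
            )
    return pd.DataFrame(rows)
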