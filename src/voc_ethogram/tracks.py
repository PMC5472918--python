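"""Arena geometry, trajectory containers, and delimited-text I/O.

Coordinates are millimetres in a vertical observation arena, origin at the
bottom-left corner with y increasing upward; a slip therefore shows up as a
decrease in y.  Positions are sampled at a fixed frame interval (0.25 s by
default) so the timestamp of frame ``k`` is implicitly ``k * dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: Default sampling interval of the tracking system, seconds per frame.
FRAME_DT = 0.25

STRAINS = ("wild_type", "p38b", "p53")
TREATMENTS = ("control", "toluene", "formaldehyde")
SESSIONS = ("pre", "post")

#: Header of the delimited trajectory table.
TRACK_COLUMNS = (
    "individual_id",
    "strain",
    "treatment",
    "session",
    "frame",
    "x_mm",
    "y_mm",
)

ZONES = ("top", "bottom", "food", "middle")


class TrackFormatError(ValueError):
    """The trajectory table is malformed (e.g. a required column is absent)."""


class FrameGapError(ValueError):
    """Frame numbers of an individual are not consecutive integers from 0."""


class ArenaBoundsError(ValueError):
    """A position lies outside the arena."""


@dataclass(frozen=True)
class FoodRegion:
    """Axis-aligned rectangle in arena coordinates (mm) marking the food patch."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("food region must have positive extent")

    def contains(self, x, y):
        return (
            (x >= self.x_min)
            & (x <= self.x_max)
            & (y >= self.y_min)
            & (y <= self.y_max)
        )

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))


def default_food_region(width: float = 50.0, height: float = 150.0) -> FoodRegion:
    """20 mm x 10 mm patch centered on the bottom edge (scaled down for small arenas)."""
    w = min(20.0, 0.4 * width)
    h = min(10.0, 0.2 * height)
    return FoodRegion((width - w) / 2.0, (width + w) / 2.0, 0.0, h)


#: Food patch of the default 50 mm x 150 mm arena.
DEFAULT_FOOD_REGION = default_food_region()


@dataclass(frozen=True)
class Arena:
    """Vertical observation arena.

    The defaults describe a 150 mm (height) x 50 mm (width) chamber whose
    uppermost 20% is the "top" zone, lowest 20% the "bottom" zone, and a
    20 mm x 10 mm food patch sits centered on the bottom edge.  All of it is
    configurable (``food_region=None`` means no food patch); the zone geometry
    is a convention of this package, not a measurement.
    """

    width: float = 50.0
    height: float = 150.0
    top_zone_fraction: float = 0.2
    bottom_zone_fraction: float = 0.2
    food_region: FoodRegion | None = DEFAULT_FOOD_REGION

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("arena dimensions must be positive")
        if not (0 < self.top_zone_fraction < 1 and 0 < self.bottom_zone_fraction < 1):
            raise ValueError("zone fractions must lie in (0, 1)")
        if self.top_zone_fraction + self.bottom_zone_fraction >= 1:
            raise ValueError("top and bottom zones must not overlap")
        if self.food_region is not None:
            fr = self.food_region
            if fr.x_min < 0 or fr.x_max > self.width or fr.y_min < 0 or fr.y_max > self.height:
                raise ValueError("food region must lie inside the arena")

    def contains(self, x, y):
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)


@dataclass
class Track:
    """One individual's fixed-rate 2-D position series with cohort labels.

    ``slip_events`` optionally records ground-truth slips injected by the
    synthetic generator as ``(start_sub_segment_index, n_steps)`` pairs; it is
    empty for observed data.
    """

    individual_id: str
    strain: str
    treatment: str
    session: str
    positions: np.ndarray
    dt: float = FRAME_DT
    slip_events: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array of (x, y) mm")
        if len(self.positions) < 2:
            raise ValueError("a track needs at least 2 positions")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def duration(self) -> float:
        """Observation span in seconds (n-1 sub-segments of dt each)."""
        return (self.n_positions - 1) * self.dt

    def displacements(self) -> np.ndarray:
        return np.diff(self.positions, axis=0)

    def validate_in(self, arena: Arena) -> None:
        inside = arena.contains(self.positions[:, 0], self.positions[:, 1])
        if not np.all(inside):
            k = int(np.argmin(inside))
            raise ArenaBoundsError(
                f"track {self.individual_id!r}: position {k} "
                f"{tuple(self.positions[k])} outside arena"
            )


@dataclass
class TrackSet:
    """A collection of tracks recorded in (or simulated for) one arena."""

    arena: Arena
    tracks: list[Track] = field(default_factory=list)

    def __post_init__(self) -> None:
        dts = {t.dt for t in self.tracks}
        if len(dts) > 1:
            raise ValueError(f"all tracks must share dt, got {sorted(dts)}")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    @property
    def dt(self) -> float:
        return self.tracks[0].dt if self.tracks else FRAME_DT

    def group_sizes(self) -> dict[tuple[str, str, str], int]:
        """Number of tracks per (strain, treatment, session)."""
        sizes: dict[tuple[str, str, str], int] = {}
        for t in self.tracks:
            key = (t.strain, t.treatment, t.session)
            sizes[key] = sizes.get(key, 0) + 1
        return sizes

    def to_frame(self) -> pd.DataFrame:
        """Long table with one row per frame, ordered by (individual, session, frame)."""
        parts = []
        for t in sorted(self.tracks, key=lambda t: (t.individual_id, t.session)):
            n = t.n_positions
            parts.append(
                pd.DataFrame(
                    {
                        "individual_id": t.individual_id,
                        "strain": t.strain,
                        "treatment": t.treatment,
                        "session": t.session,
                        "frame": np.arange(n),
                        "x_mm": t.positions[:, 0],
                        "y_mm": t.positions[:, 1],
                    }
                )
            )
        if not parts:
            return pd.DataFrame(columns=TRACK_COLUMNS)
        return pd.concat(parts, ignore_index=True)


def write_tracks(trackset: TrackSet, path: str | Path) -> Path:
    """Write a trajectory table as comma-delimited text.

    Rows are ordered by (individual_id, session, frame) and coordinates are
    printed with 6 decimal places, so write -> read -> write is byte-stable.
    """
    path = Path(path)
    df = trackset.to_frame()
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_tracks(
    path: str | Path, arena: Arena | None = None, dt: float = FRAME_DT
) -> TrackSet:
    """Read a comma-delimited trajectory table into a :class:`TrackSet`.

    Raises :class:`TrackFormatError` for a missing column,
    :class:`FrameGapError` when an individual's frames are not consecutive
    integers starting at 0, and :class:`ArenaBoundsError` (naming the
    offending file row) for a position outside the arena.
    """
    arena = arena if arena is not None else Arena()
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        return TrackSet(arena, [])

    outside = ~arena.contains(df["x_mm"].to_numpy(), df["y_mm"].to_numpy())
    if outside.any():
        row = int(np.flatnonzero(outside)[0])
        raise ArenaBoundsError(
            f"position outside arena at file row {row + 2} "
            f"(x={df['x_mm'].iloc[row]}, y={df['y_mm'].iloc[row]})"
        )

    tracks: list[Track] = []
    for (ind, session), g in df.groupby(["individual_id", "session"], sort=True):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        expected = np.arange(len(frames))
        if not np.array_equal(frames, expected):
            raise FrameGapError(
                f"individual {ind!r} session {session!r}: frames are not "
                "consecutive integers from 0"
            )
        strains = g["strain"].unique()
        treats = g["treatment"].unique()
        if len(strains) > 1 or len(treats) > 1:
            raise TrackFormatError(
                f"individual {ind!r} session {session!r} has inconsistent labels"
            )
        tracks.append(
            Track(
                individual_id=str(ind),
                strain=str(strains[0]),
                treatment=str(treats[0]),
                session=str(session),
                positions=np.column_stack(
                    [g["x_mm"].to_numpy(float), g["y_mm"].to_numpy(float)]
                ),
                dt=dt,
            )
        )
    return TrackSet(arena, tracks)


def zones_of(xy: np.ndarray, arena: Arena) -> np.ndarray:
    """Vectorized zone labels for an (n, 2) array of in-bounds positions.

    Precedence: food patch first, then top band (y >= (1 - top_fraction) * h),
    then bottom band (y <= bottom_fraction * h), else middle.
    """
    xy = np.asarray(xy, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    inside = arena.contains(x, y)
    if not np.all(inside):
        k = int(np.argmin(inside))
        raise ArenaBoundsError(f"position {tuple(xy[k])} outside arena")
    top_y = (1.0 - arena.top_zone_fraction) * arena.height
    bot_y = arena.bottom_zone_fraction * arena.height
    food = (
        arena.food_region.contains(x, y)
        if arena.food_region is not None
        else np.zeros(len(xy), dtype=bool)
    )
    return np.select(
        [food, y >= top_y, y <= bot_y], ["food", "top", "bottom"], default="middle"
    ).astype(object)


def zone_of(position: Sequence[float], arena: Arena) -> str:
    """Zone label in {top, bottom, food, middle} of a single position."""
    return str(zones_of(np.asarray(position, dtype=float)[None, :], arena)[0])
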