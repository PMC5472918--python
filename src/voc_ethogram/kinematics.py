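"""Segment-wise movement parameters.

Tracks sampled at 0.25 s/frame are cut into non-overlapping 5-s segments of
20 sub-segments each, and six parameters are computed per segment:

* speed (mm/s): total sub-segment path length divided by 5 s;
* acceleration (mm/s^2): mean absolute difference of consecutive sub-segment
  speeds divided by 0.25 s;
* locomotory rate (mm/s): path length divided by moving time only
  (undefined, NaN, for a fully stopped segment);
* meander (rad/mm): accumulated absolute heading change between consecutive
  moving sub-segments per moving path length (undefined with < 2 moving
  sub-segments);
* stop duration (s): 0.25 s per sub-segment whose displacement is strictly
  below 0.1 mm (a tenth of a body length);
* slipping number: maximal runs of sub-segments whose downward vertical
  displacement exceeds 2 mm; each run counts as one slip event.

Undefined values propagate as NaN; they are never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import Arena, Track, TrackSet, zones_of, ZONES

SUB_DT = 0.25
SUBSTEPS = 20
SEGMENT_SECONDS = SUB_DT * SUBSTEPS

#: Displacement below which a sub-segment counts as stopped (mm, strict).
STOP_DISPLACEMENT_MM = 0.1

#: Default downward displacement that qualifies a sub-segment as slipping
#: (mm per 0.25 s, i.e. 8 mm/s -- roughly twice the fastest group mean speed).
SLIP_THRESHOLD_MM = 2.0

FEATURE_COLUMNS = (
    "speed",
    "acceleration",
    "locomotory_rate",
    "meander",
    "stop_duration",
    "slipping_number",
)
LABEL_COLUMNS = ("individual_id", "strain", "treatment", "session", "segment")


class SamplingError(ValueError):
    """The track is not sampled at the 0.25-s frame interval the formulas assume."""


@dataclass
class Segment:
    """One 5-s window: 20 consecutive 0.25-s displacement vectors (mm)."""

    displacements: np.ndarray
    start_index: int = 0

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.shape != (SUBSTEPS, 2):
            raise ValueError(f"a segment holds exactly {SUBSTEPS} displacement vectors")

    @property
    def magnitudes(self) -> np.ndarray:
        return np.hypot(self.displacements[:, 0], self.displacements[:, 1])


def segment_track(track: Track) -> list[Segment]:
    """Cut a track into floor((n_positions - 1) / 20) segments; the trailing
    partial window is discarded."""
    if not np.isclose(track.dt, SUB_DT):
        raise SamplingError(
            f"track dt is {track.dt} s; the segment formulas assume {SUB_DT} s "
            "(resampling is out of scope)"
        )
    disp = track.displacements()
    n_seg = len(disp) // SUBSTEPS
    return [
        Segment(disp[i * SUBSTEPS : (i + 1) * SUBSTEPS], start_index=i * SUBSTEPS)
        for i in range(n_seg)
    ]


def compute_speed(segment: Segment) -> float:
    """Path length of the 20 sub-segments divided by 5 s (mm/s)."""
    return float(segment.magnitudes.sum() / SEGMENT_SECONDS)


def compute_acceleration(segment: Segment) -> float:
    """Mean over the 19 consecutive sub-segment pairs of |v(k+1) - v(k)| / 0.25,
    with v(k) the k-th sub-segment speed (mm/s^2)."""
    v = segment.magnitudes / SUB_DT
    return float(np.abs(np.diff(v)).mean() / SUB_DT)


def compute_stop_duration(segment: Segment) -> float:
    """0.25 s per sub-segment displaced strictly less than 0.1 mm."""
    return float((segment.magnitudes < STOP_DISPLACEMENT_MM).sum() * SUB_DT)


def compute_locomotory_rate(segment: Segment) -> float:
    """Path length divided by (5 s - stop time); NaN when fully stopped."""
    stop = compute_stop_duration(segment)
    if stop >= SEGMENT_SECONDS:
        return float("nan")
    return float(segment.magnitudes.sum() / (SEGMENT_SECONDS - stop))


def compute_meander(segment: Segment) -> float:
    """Sum of |heading change| between consecutive moving sub-segments divided
    by the moving path length (rad/mm); NaN with fewer than 2 moving
    sub-segments.  Stopped sub-segments are skipped -- their heading is
    tracker noise."""
    mags = segment.magnitudes
    moving = mags >= STOP_DISPLACEMENT_MM
    if moving.sum() < 2:
        return float("nan")
    d = segment.displacements[moving]
    headings = np.arctan2(d[:, 1], d[:, 0])
    turns = np.diff(headings)
    turns = (turns + np.pi) % (2.0 * np.pi) - np.pi
    return float(np.abs(turns).sum() / mags[moving].sum())


def count_slips(segment: Segment, slip_threshold: float = SLIP_THRESHOLD_MM) -> int:
    """Number of maximal runs of sub-segments whose downward displacement
    exceeds ``slip_threshold`` mm; each run is one slip event."""
    dy = segment.displacements[:, 1]
    slipping = dy < -slip_threshold
    if not slipping.any():
        return 0
    starts = slipping & ~np.concatenate(([False], slipping[:-1]))
    return int(starts.sum())


def segment_features(segment: Segment, slip_threshold: float = SLIP_THRESHOLD_MM) -> dict:
    return {
        "speed": compute_speed(segment),
        "acceleration": compute_acceleration(segment),
        "locomotory_rate": compute_locomotory_rate(segment),
        "meander": compute_meander(segment),
        "stop_duration": compute_stop_duration(segment),
        "slipping_number": count_slips(segment, slip_threshold),
    }


def extract_features(
    trackset: TrackSet, slip_threshold: float = SLIP_THRESHOLD_MM
) -> pd.DataFrame:
    """Tidy feature table: one row per 5-s segment with cohort labels.

    Columns are ``LABEL_COLUMNS + FEATURE_COLUMNS``; undefined meander or
    locomotory rate appear as NaN.
    """
    rows = []
    for track in trackset:
        segs = segment_track(track)
        if not segs:
            continue
        disp = np.stack([s.displacements for s in segs])  # (n_seg, 20, 2)
        mags = np.hypot(disp[..., 0], disp[..., 1])
        path = mags.sum(axis=1)
        speed = path / SEGMENT_SECONDS
        v = mags / SUB_DT
        accel = np.abs(np.diff(v, axis=1)).mean(axis=1) / SUB_DT
        stopped = mags < STOP_DISPLACEMENT_MM
        stop_dur = stopped.sum(axis=1) * SUB_DT
        move_time = SEGMENT_SECONDS - stop_dur
        with np.errstate(divide="ignore", invalid="ignore"):
            loco = np.where(move_time > 0, path / np.where(move_time > 0, move_time, 1.0), np.nan)
        slip_step = disp[..., 1] < -slip_threshold
        starts = slip_step & ~np.concatenate(
            [np.zeros((len(segs), 1), dtype=bool), slip_step[:, :-1]], axis=1
        )
        slips = starts.sum(axis=1)
        meander = np.array([compute_meander(s) for s in segs])
        rows.append(
            pd.DataFrame(
                {
                    "individual_id": track.individual_id,
                    "strain": track.strain,
                    "treatment": track.treatment,
                    "session": track.session,
                    "segment": np.arange(len(segs)),
                    "speed": speed,
                    "acceleration": accel,
                    "locomotory_rate": loco,
                    "meander": meander,
                    "stop_duration": stop_dur,
                    "slipping_number": slips.astype(float),
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=list(LABEL_COLUMNS) + list(FEATURE_COLUMNS))
    return pd.concat(rows, ignore_index=True)


@dataclass
class OccupancyResult:
    """Stay durations (s) per zone, per 30-s window and overall."""

    windows: pd.DataFrame  # columns: window, top, bottom, food, middle
    totals: dict[str, float]

    @property
    def total_duration(self) -> float:
        return float(sum(self.totals.values()))


def zone_occupancy(
    track: Track, arena: Arena, window_s: float = 30.0
) -> OccupancyResult:
    """Assign each 0.25-s sub-segment to the zone of its end position and
    accumulate stay durations per 30-s window; the last window may be short."""
    ends = track.positions[1:]
    zones = zones_of(ends, arena)
    n = len(ends)
    t_start = np.arange(n) * track.dt
    window = (t_start // window_s).astype(int)
    df = pd.DataFrame({"window": window, "zone": zones, "dur": track.dt})
    wide = (
        df.pivot_table(index="window", columns="zone", values="dur", aggfunc="sum")
        .reindex(columns=list(ZONES), fill_value=0.0)
        .fillna(0.0)
        .reset_index()
    )
    wide.columns.name = None
    totals = {z: float(wide[z].sum()) for z in ZONES}
    return OccupancyResult(windows=wide, totals=totals)


def occupancy_table(
    trackset: TrackSet, window_s: float = 30.0
) -> pd.DataFrame:
    """Overall per-track zone durations (s) with cohort labels."""
    rows = []
    for t in trackset:
        occ = zone_occupancy(t, trackset.arena, window_s)
        rows.append(
            {
                "individual_id": t.individual_id,
                "strain": t.strain,
                "treatment": t.treatment,
                "session": t.session,
                **occ.totals,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["individual_id", "strain", "treatment", "session", *ZONES],
    )
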