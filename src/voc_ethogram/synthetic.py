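"""Synthetic fly trajectories with controllable kinematic structure.

No raw trajectory recordings from the inhalation-screening study were ever
deposited, so this module generates surrogate tracks with the statistical
structure the downstream analysis assumes: a two-state (move/stop) Markov
chain over 0.25-s steps, a correlated random walk while moving with an upward
(negative-geotaxis) heading bias, and Poisson-arriving "slip" events -- abrupt
downward drops on the vertical arena wall -- injected as labeled ground truth.

The default presets pin the nominal speed and slip count of each strain x
treatment group to the study's printed group means, so parameter-recovery
tests are well posed.  Everything not printed (stop-bout structure, turning
spread, geotaxis bias, gait variability) is a documented design choice; see
docs/methods.md.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .tracks import FRAME_DT, Arena, Track, TrackSet

#: Displacement of a "stopped" step is drawn uniformly below this (mm); the
#: kinematics stage counts sub-segments under 0.1 mm as stopped.
STOP_DISP_MAX = 0.08
_STOP_DISP_MEAN = STOP_DISP_MAX / 2.0

#: Nominal vertical drop of one slip step (mm per 0.25 s).  Just above the
#: 2 mm detector threshold so every injected slip is detectable while keeping
#: the slip contribution to path length compatible with the printed speeds.
SLIP_DROP_MEAN = 2.2
_SLIP_DROP_LO, _SLIP_DROP_HI = 2.05, 2.6

#: Hard cap on slip events injected per 5-s block (20 steps with a mandatory
#: non-slip step between events).
MAX_SLIPS_PER_BLOCK = 5

_BLOCK = 20  # sub-segments per 5-s block at 0.25 s/frame


class ParameterError(ValueError):
    """A preset is inconsistent with the arena or simulation settings."""


class ConfigurationError(ValueError):
    """A requested group has no preset."""


@dataclass(frozen=True)
class BehaviorPreset:
    """Generative parameters of one strain x treatment group.

    ``move_speed_mean``/``move_speed_sd`` are the nominal grand-mean segment
    speed (mm/s) and its between-individual SD; the simulator back-solves the
    while-moving step speed so that the downstream 5-s segment speed estimator
    recovers ``move_speed_mean`` on average.  ``slip_rate`` is the expected
    number of slip events per 5-s segment (``slip_rate_sd`` its
    between-individual SD).  ``speed_jitter_frac`` is the within-gait step
    length variability (SD as a fraction of the mean step); it is the main
    determinant of the acceleration parameter.
    """

    name: str
    move_speed_mean: float
    move_speed_sd: float
    p_stop_entry: float
    p_stop_exit: float
    turn_sd: float
    geotaxis_drift: float
    slip_rate: float
    slip_depth_mean: float = SLIP_DROP_MEAN
    slip_rate_sd: float = 0.0
    food_attraction: float = 0.0
    speed_jitter_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.move_speed_mean <= 0:
            raise ValueError("move_speed_mean must be positive")
        for p in (self.p_stop_entry, self.p_stop_exit):
            if not (0.0 <= p <= 1.0):
                raise ValueError("stop probabilities must lie in [0, 1]")
        if self.slip_rate < 0 or self.slip_rate_sd < 0:
            raise ValueError("slip rate must be non-negative")
        if not (-1.0 <= self.geotaxis_drift <= 1.0):
            raise ValueError("geotaxis_drift must lie in [-1, 1]")
        if self.food_attraction < 0:
            raise ValueError("food_attraction must be non-negative")
        if self.move_speed_sd < 0 or self.turn_sd < 0:
            raise ValueError("spreads must be non-negative")
        if not (0.0 <= self.speed_jitter_frac < 1.5):
            raise ValueError("speed_jitter_frac out of range")

    @property
    def stop_fraction(self) -> float:
        """Stationary fraction of time in the stopped state."""
        s = self.p_stop_entry + self.p_stop_exit
        if s == 0:
            return 0.0
        return self.p_stop_entry / s


@dataclass(frozen=True)
class SimulationConfig:
    """Observation design: arena, frame interval, session length, cohort size."""

    arena: Arena = field(default_factory=Arena)
    dt: float = FRAME_DT
    duration: float = 1800.0
    n_individuals: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError("duration must be a positive multiple of dt")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


#: Walking steps are capped just below the 2-mm slip-detector threshold so a
#: fast gait can never masquerade as a slip; only injected falls exceed it.
STEP_CAP_MM = 1.9


def _capped_folded_mean(mu: float, sigma: float, cap: float) -> float:
    """E[min(|X|, cap)] for X ~ N(mu, sigma^2)."""
    if sigma <= 0:
        return min(abs(mu), cap)
    folded = sigma * np.sqrt(2.0 / np.pi) * np.exp(-(mu * mu) / (2 * sigma * sigma)) + mu * (
        1.0 - 2.0 * norm.cdf(-mu / sigma)
    )

    def excess(m):
        z = (m - cap) / sigma
        return (m - cap) * norm.cdf(z) + sigma * norm.pdf(z)

    return folded - excess(mu) - excess(-mu)


def _solve_step_mu(target: float, jitter_frac: float, cap: float = STEP_CAP_MM) -> float:
    """Location mu such that min(|N(mu, (f*mu)^2)|, cap) has mean ``target``.

    Inverts the folding and capping bias so the downstream speed estimator is
    unbiased.  Targets within 3% of the cap are clamped (the cap is then the
    binding constraint and the residual bias is negligible at cohort level).
    """
    target = min(target, 0.97 * cap)
    if jitter_frac <= 0:
        return target
    lo, hi = 1e-9, cap * 4.0
    f = lambda m: _capped_folded_mean(m, jitter_frac * m, cap) - target
    if f(hi) < 0:
        return hi
    return float(brentq(f, lo, hi, xtol=1e-10))


def _wrap(angle):
    return (angle + np.pi) % (2.0 * np.pi) - np.pi


def _step_speed(preset: BehaviorPreset, speed_i: float, slip_rate_i: float) -> float:
    """While-moving step speed (mm/s) that yields ``speed_i`` as the expected
    5-s segment speed, accounting for stop time, stop dribble, and slip falls.

    The slip-path term is capped at 45% of the total path: beyond that the
    fly could not climb back what it falls (slips are gated on wall height),
    so budgeting the nominal slip path would starve the walking speed without
    buying any realized slips.
    """
    f_stop = preset.stop_fraction
    slip_path = min(
        slip_rate_i * preset.slip_depth_mean, 0.45 * 5.0 * speed_i
    )
    slip_steps = slip_path / preset.slip_depth_mean
    non_slip = _BLOCK - slip_steps
    budget = 5.0 * speed_i - slip_path - non_slip * f_stop * _STOP_DISP_MEAN
    denom = non_slip * (1.0 - f_stop) * FRAME_DT
    if denom <= 0:
        return 0.05
    return max(budget / denom, 0.05)


def _place_slips(rng: np.random.Generator, rate: float) -> np.ndarray:
    """Start indices (within a 20-step block) of this block's slip events.

    Events are single steps, never at index 0 and never adjacent, so maximal
    downward runs in the analysis correspond one-to-one to injected events.
    """
    if rate <= 0:
        return np.empty(0, dtype=int)
    n = int(min(rng.poisson(rate), MAX_SLIPS_PER_BLOCK))
    if n == 0:
        return np.empty(0, dtype=int)
    # starts s_1 < ... < s_n in [1, 19] with s_{i+1} >= s_i + 2
    base = rng.choice(np.arange(1, _BLOCK - n + 1), size=n, replace=False)
    base.sort()
    return base + np.arange(n)


def generate_track(
    preset: BehaviorPreset,
    config: SimulationConfig,
    individual_seed: int,
    *,
    individual_id: str = "fly-00",
    strain: str = "wild_type",
    treatment: str = "control",
    session: str = "pre",
) -> Track:
    """Simulate one individual.  Identical seeds give bit-identical tracks."""
    arena = config.arena
    if preset.slip_depth_mean > arena.height:
        raise ParameterError(
            f"slip_depth_mean {preset.slip_depth_mean} mm exceeds arena height"
        )
    rng = np.random.default_rng(int(individual_seed))
    dt = config.dt
    n_steps = config.n_steps

    # Individual-level heterogeneity: each fly draws its own nominal speed and
    # slip rate, so the n = 15 group dispersion matches the printed SDs.
    speed_i = max(0.2, rng.normal(preset.move_speed_mean, preset.move_speed_sd))
    slip_rate_i = (
        max(0.0, rng.normal(preset.slip_rate, preset.slip_rate_sd))
        if preset.slip_rate > 0
        else 0.0
    )
    v_step = _step_speed(preset, speed_i, slip_rate_i)
    step_mu = _solve_step_mu(v_step * dt, preset.speed_jitter_frac)
    step_sd = preset.speed_jitter_frac * step_mu

    # Slip schedule, one Poisson draw per complete 5-s block.
    n_blocks = n_steps // _BLOCK
    slip_drop = np.zeros(n_steps)
    for b in range(n_blocks):
        starts = _place_slips(rng, slip_rate_i)
        for s in starts:
            k = b * _BLOCK + int(s)
            slip_drop[k] = np.clip(
                rng.normal(preset.slip_depth_mean, 0.1), _SLIP_DROP_LO, _SLIP_DROP_HI
            )

    # Pre-drawn per-step randomness (the walk itself is sequential).
    u_trans = rng.random(n_steps)
    turns = rng.normal(0.0, preset.turn_sd, n_steps)
    steps_mov = np.minimum(np.abs(rng.normal(step_mu, step_sd, n_steps)), STEP_CAP_MM)
    stop_disp = rng.uniform(0.0, STOP_DISP_MAX, n_steps)
    stop_ang = rng.uniform(-np.pi, np.pi, n_steps)
    slip_dx = rng.normal(0.0, 0.15, n_steps)

    w, h = arena.width, arena.height
    x = rng.uniform(0.1 * w, 0.9 * w)
    y = rng.uniform(0.1 * h, 0.9 * h)
    heading = rng.uniform(-np.pi, np.pi)
    f_stop = preset.stop_fraction
    moving = rng.random() >= f_stop
    g = preset.geotaxis_drift
    fa = preset.food_attraction
    food_xy = arena.food_region.center if arena.food_region is not None else None
    up = np.pi / 2.0

    pos = np.empty((n_steps + 1, 2))
    pos[0] = (x, y)
    slip_events: list[tuple[int, int]] = []
    for t in range(n_steps):
        if slip_drop[t] > 0.0 and y >= slip_drop[t]:
            # a slip needs wall height to fall from: scheduled events are
            # skipped while the fly is on the floor, so every realized slip
            # is a full, detectable drop and is recorded as ground truth
            slip_events.append((t, 1))
            x += slip_dx[t]
            y -= slip_drop[t]
            # negative-geotaxis righting response: climb after a fall
            heading = up
        else:
            if moving:
                if u_trans[t] < preset.p_stop_entry:
                    moving = False
            else:
                if u_trans[t] < preset.p_stop_exit:
                    moving = True
            if moving:
                heading = heading + turns[t]
                if g:
                    # climb upward; near the ceiling, patrol along the top
                    # edge instead of driving into the wall
                    if y < 0.95 * h:
                        goal = up
                    else:
                        goal = 0.0 if np.cos(heading) >= 0.0 else np.pi
                    heading = heading + g * _wrap(goal - heading)
                if fa and food_xy is not None:
                    goal = np.arctan2(food_xy[1] - y, food_xy[0] - x)
                    heading = heading + fa * _wrap(goal - heading)
                heading = _wrap(heading)
                step = steps_mov[t]
                x += step * np.cos(heading)
                y += step * np.sin(heading)
            else:
                x += stop_disp[t] * np.cos(stop_ang[t])
                y += stop_disp[t] * np.sin(stop_ang[t])
        # reflect at the walls (displacements are small relative to the arena)
        if x < 0.0:
            x = -x
            heading = _wrap(np.pi - heading)
        elif x > w:
            x = 2.0 * w - x
            heading = _wrap(np.pi - heading)
        if y < 0.0:
            y = -y
            heading = _wrap(-heading)
        elif y > h:
            y = 2.0 * h - y
            heading = _wrap(-heading)
        pos[t + 1] = (x, y)

    return Track(
        individual_id=individual_id,
        strain=strain,
        treatment=treatment,
        session=session,
        positions=pos,
        dt=dt,
        slip_events=tuple(slip_events),
    )


def _child_seed(master: int, *keys) -> int:
    """Deterministic per-individual seed below 2**31 derived from the master."""
    ints = [int(master) & 0xFFFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return int(np.random.SeedSequence(ints).generate_state(1)[0]) & 0x7FFFFFFF


GroupKey = tuple[str, str]  # (strain, treatment)


def generate_cohort(
    presets: Mapping[GroupKey, BehaviorPreset],
    config: SimulationConfig,
    session: str = "pre",
) -> TrackSet:
    """``config.n_individuals`` tracks per group, deterministic in ``config.seed``."""
    tracks = []
    for strain, treatment in sorted(presets):
        preset = presets[(strain, treatment)]
        for i in range(config.n_individuals):
            seed = _child_seed(config.seed, strain, treatment, session, i)
            tracks.append(
                generate_track(
                    preset,
                    config,
                    seed,
                    individual_id=f"{strain}-{treatment}-{i + 1:02d}",
                    strain=strain,
                    treatment=treatment,
                    session=session,
                )
            )
    return TrackSet(config.arena, tracks)


def generate_study(
    config: SimulationConfig,
    presets: Mapping[GroupKey, BehaviorPreset] | None = None,
    groups: list[GroupKey] | None = None,
) -> TrackSet:
    """Pre/post observation design of the screening study.

    For every (strain, treatment) group, the *pre* session is generated from
    the strain's control preset (flies are observed before exposure) and the
    *post* session from the group's own preset.  Individual ids are stable
    across the two sessions of a group.
    """
    presets = presets if presets is not None else default_presets()
    keys = sorted(groups if groups is not None else presets)
    tracks = []
    for strain, treatment in keys:
        try:
            pre_preset = presets[(strain, "control")]
            post_preset = presets[(strain, treatment)]
        except KeyError as exc:
            raise ConfigurationError(f"no preset for group {exc}") from exc
        for i in range(config.n_individuals):
            ind = f"{strain}-{treatment}-{i + 1:02d}"
            for session, preset in (("pre", pre_preset), ("post", post_preset)):
                seed = _child_seed(config.seed, strain, treatment, session, i)
                tracks.append(
                    generate_track(
                        preset,
                        config,
                        seed,
                        individual_id=ind,
                        strain=strain,
                        treatment=treatment,
                        session=session,
                    )
                )
    return TrackSet(config.arena, tracks)


def _stop_entry(stop_seconds: float, exit_p: float = 0.2) -> float:
    """Per-step stop-entry probability giving a stationary stop time of
    ``stop_seconds`` per 5-s segment, with mean stop bouts of 1/exit_p steps."""
    f = stop_seconds / 5.0
    return exit_p * f / (1.0 - f)


def default_presets() -> dict[GroupKey, BehaviorPreset]:
    """The nine strain x treatment presets of the screening study.

    Nominal speeds and slip rates (with their SDs) equal the printed group
    statistics; control groups describe unexposed behavior.  Stop durations,
    turning spread, geotaxis bias, gait variability, and food attraction are
    design choices that realize the study's qualitative contrasts: exposure
    lowers speed, acceleration, and locomotory rate and raises stop duration,
    meander, and slipping, with stronger effects of formaldehyde than toluene
    and the largest behavioral shift in the p38b mutant.
    """
    # (speed mean, speed sd, slip rate, slip sd, stop s/5s, turn sd, drift)
    table: dict[GroupKey, tuple[float, float, float, float, float, float, float]] = {
        ("wild_type", "control"): (3.52, 0.40, 0.85, 0.10, 1.00, 0.50, 0.10),
        ("wild_type", "toluene"): (3.12, 0.27, 1.23, 0.13, 1.40, 0.80, 0.26),
        ("wild_type", "formaldehyde"): (2.66, 0.22, 2.91, 0.28, 1.60, 0.95, 0.26),
        ("p38b", "control"): (4.22, 0.41, 0.94, 0.09, 0.60, 0.45, 0.08),
        ("p38b", "toluene"): (2.66, 0.26, 2.05, 0.25, 1.30, 0.85, 0.30),
        ("p38b", "formaldehyde"): (2.18, 0.18, 4.03, 0.48, 1.00, 1.00, 0.30),
        ("p53", "control"): (2.72, 0.25, 1.04, 0.11, 1.60, 0.55, 0.06),
        ("p53", "toluene"): (2.10, 0.20, 1.83, 0.20, 2.20, 0.80, 0.18),
        ("p53", "formaldehyde"): (2.25, 0.21, 2.09, 0.20, 2.20, 0.85, 0.22),
    }
    presets: dict[GroupKey, BehaviorPreset] = {}
    for (strain, treatment), row in table.items():
        speed, speed_sd, slip, slip_sd, stop_s, turn_sd, drift = row
        control = treatment == "control"
        presets[(strain, treatment)] = BehaviorPreset(
            name=f"{strain}/{treatment}",
            move_speed_mean=speed,
            move_speed_sd=speed_sd,
            p_stop_entry=_stop_entry(stop_s),
            p_stop_exit=0.2,
            turn_sd=turn_sd,
            geotaxis_drift=drift,
            slip_rate=slip,
            slip_rate_sd=slip_sd,
            food_attraction=0.04 if control else 0.01,
            speed_jitter_frac=0.8 if control else 0.2,
        )
    return presets
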