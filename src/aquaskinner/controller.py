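"""Closed observe-decide-actuate trial loop.

Each tick the controller, per channel: obtains an observation (a camera
frame or a direct position from the simulator), updates the track
state, works out the current quadrant lighting (including any scheduled
rotation), evaluates the shock rules on the smoothed position, applies
yoked-control pairing, and appends a row to the trial log.  Execution
is in simulated time driven by the tick counter — the physical device's
25 Hz is a capability ceiling, not a semantic — so runs are exactly
reproducible.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .arena import ArenaGeometry, Quadrant, quadrant_of
from .tracking import QCFlag, TrackState, TrackingParams, init_background, track_frame

__all__ = [
    "LightSpec",
    "TrialPhase",
    "ShockTrigger",
    "ShockRule",
    "ShockCommand",
    "PhaseSchedule",
    "TrialConfig",
    "ChannelTimers",
    "LOG_COLUMNS",
    "build_phase_schedule",
    "quantize_duration",
    "rotation_state",
    "lighting_at",
    "evaluate_shock",
    "yoke",
    "run_trial",
]

MAX_TICK_RATE_HZ = 25.0
STEP_MS = 8
MAX_LIGHT_LEVEL = 10


def _check_level(v) -> int:
    if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
        raise ValueError(f"light level must be an integer, got {v!r}")
    if not (0 <= v <= MAX_LIGHT_LEVEL):
        raise ValueError(f"light level {v} outside 0..{MAX_LIGHT_LEVEL}")
    return int(v)


@dataclass(frozen=True)
class LightSpec:
    """Per-quadrant red and blue intensities.

    Each colour runs from off (0) to full brightness (10) in ten even
    steps.  Red is background illumination the camera sees through its
    filter-free band; blue is the stimulus colour the animals perceive.
    Indices follow config-frame quadrants Q1..Q4.
    """

    red: Tuple[int, int, int, int] = (2, 2, 2, 2)
    blue: Tuple[int, int, int, int] = (0, 0, 0, 0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "red", tuple(_check_level(v) for v in self.red))
        object.__setattr__(self, "blue", tuple(_check_level(v) for v in self.blue))
        if len(self.red) != 4 or len(self.blue) != 4:
            raise ValueError("light spec needs exactly four quadrant levels per colour")


@dataclass(frozen=True)
class ShockTrigger:
    """AND-combined trigger conditions for a shock rule.

    ``in_quadrants`` names quadrants in the *configuration frame*: as
    the lighting pattern rotates, the punished region follows it.
    Distance conditions are on the smoothed position; the speed
    condition compares the trailing mean speed over ``window_s``
    against ``speed_lt`` (for "keep moving" trials).
    """

    in_quadrants: Optional[frozenset] = None
    edge_distance_lt: Optional[float] = None
    center_distance_lt: Optional[float] = None
    speed_lt: Optional[float] = None
    window_s: float = 5.0


@dataclass(frozen=True)
class ShockRule:
    trigger: ShockTrigger
    current_mA: float = 1.2
    waveform_hz: float = 100.0
    duration_ms: int = 96
    delay_s: float = 0.0
    refractory_s: float = 10.0

    def __post_init__(self) -> None:
        grid = round(self.current_mA / 0.2)
        if not (0.2 - 1e-9 <= self.current_mA <= 20.0 + 1e-9) or abs(
            grid * 0.2 - self.current_mA
        ) > 1e-9:
            raise ValueError("current_mA must lie on the 0.2..20 mA grid in 0.2 mA steps")
        if not (10.0 <= self.waveform_hz <= 1000.0):
            raise ValueError("waveform_hz must lie in 10..1000 Hz")
        if self.duration_ms < 48 or self.duration_ms % 48 != 0:
            raise ValueError("duration_ms must be a positive multiple of 48 ms")
        if self.delay_s < 0 or self.refractory_s < 0:
            raise ValueError("delay_s and refractory_s must be non-negative")


@dataclass(frozen=True)
class ShockCommand:
    current_mA: float
    waveform_hz: float
    duration_ms: int


@dataclass(frozen=True)
class RotationSpec:
    angle_deg: int = 90
    interval_s: float = 600.0

    def __post_init__(self) -> None:
        if self.angle_deg not in (0, 90, 180):
            raise ValueError("rotation angle must be 0, 90 or 180 degrees")
        if self.angle_deg != 0 and self.interval_s <= 0:
            raise ValueError("rotation interval must be positive")


@dataclass(frozen=True)
class TrialPhase:
    """One block of a trial (baseline / training / rest / test)."""

    name: str
    duration_s: float
    light_spec: LightSpec = LightSpec()
    rotation: Optional[RotationSpec] = None
    shock_rules: Tuple[ShockRule, ...] = ()

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("phase duration must be positive")


@dataclass(frozen=True)
class PhaseSchedule:
    """The rotating source/sink excitation pattern.

    Phase ``p`` drives electrodes ``{p, p+1}`` as sources and the two
    opposite electrodes ``{p+3, p+4}`` as sinks (mod 6); every
    ``step_ms`` the pattern advances one electrode, so a full rotation
    takes ``n_electrodes * step_ms`` = 48 ms — the shortest shock the
    device can deliver.  Over one rotation each electrode sources
    twice and sinks twice at equal magnitude, so the delivered charge
    is net balanced and no ionic gradients accumulate.
    """

    n_electrodes: int = 6
    step_ms: int = STEP_MS

    @property
    def n_phases(self) -> int:
        return self.n_electrodes

    @property
    def rotation_ms(self) -> int:
        return self.n_electrodes * self.step_ms

    def phase_roles(self) -> List[Tuple[Tuple[int, int], Tuple[int, int]]]:
        """(sources, sinks) electrode indices for each phase."""
        n = self.n_electrodes
        half = n // 2
        out = []
        for p in range(n):
            sources = (p % n, (p + 1) % n)
            sinks = ((p + half) % n, (p + half + 1) % n)
            out.append((sources, sinks))
        return out


def build_phase_schedule(n_electrodes: int = 6, step_ms: int = STEP_MS) -> PhaseSchedule:
    """Construct the rotating excitation schedule.

    Requires an even electrode count of at least 4 so that every source
    pair has a well-defined opposite sink pair.
    """
    if n_electrodes < 4 or n_electrodes % 2 != 0:
        raise ValueError("n_electrodes must be even and >= 4")
    if step_ms <= 0:
        raise ValueError("step_ms must be positive")
    return PhaseSchedule(n_electrodes=n_electrodes, step_ms=step_ms)


def quantize_duration(requested_ms: float, rotation_ms: int = 48) -> int:
    """Snap a requested shock duration onto the rotation grid.

    Durations are floored to the largest whole number of electrode
    rotations (never exceeding the request, so never more charge than
    asked for) but never below one full rotation, the minimum
    deliverable shock.
    """
    if requested_ms <= 0:
        raise ValueError("requested duration must be positive")
    k = int(requested_ms // rotation_ms)
    return max(k, 1) * rotation_ms


def rotation_state(t_s: float, phase: TrialPhase) -> int:
    """Number of rotation events that have occurred by time ``t_s``
    within the phase (events at interval, 2*interval, ...; none at 0)."""
    rot = phase.rotation
    if rot is None or rot.angle_deg == 0:
        return 0
    return int(t_s // rot.interval_s)


def _config_quadrant(physical: Quadrant, phase: TrialPhase, t_s: float) -> Quadrant:
    """Config-frame quadrant whose lighting currently covers ``physical``.

    A clockwise rotation by 90 deg moves config quadrant ``k``'s light
    to physical sector ``k-1``, so the config quadrant seen at physical
    sector ``q`` after ``j`` events is ``q + j*steps (mod 4)``.
    """
    rot = phase.rotation
    if rot is None or rot.angle_deg == 0:
        return physical
    steps = rot.angle_deg // 90
    j = rotation_state(t_s, phase)
    return Quadrant((physical.value + j * steps) % 4)


def lighting_at(phase: TrialPhase, t_s: float) -> Tuple[Tuple[int, ...], Tuple[int, ...]]:
    """(red, blue) levels by *physical* quadrant at time ``t_s`` into the phase."""
    red = [0, 0, 0, 0]
    blue = [0, 0, 0, 0]
    for q in Quadrant:
        cfg = _config_quadrant(q, phase, t_s)
        red[q.value] = phase.light_spec.red[cfg.value]
        blue[q.value] = phase.light_spec.blue[cfg.value]
    return tuple(red), tuple(blue)


@dataclass
class ChannelTimers:
    """Per-channel shock bookkeeping: refractory and pending-delay state."""

    last_onset_s: float = -math.inf
    pending_since_s: Optional[float] = None


def evaluate_shock(
    state: TrackState,
    rule: ShockRule,
    t_s: float,
    timers: ChannelTimers,
    phase: TrialPhase,
    phase_t_s: float,
    g: ArenaGeometry,
    mean_speed_mm_s: float = 0.0,
) -> Optional[ShockCommand]:
    """Evaluate one shock rule for one channel at one tick.

    The trigger is tested on the smoothed position against the
    *current* (post-rotation) quadrant assignment.  A triggered rule
    still waits out its onset delay and its refractory interval, and a
    QC-rejected tick never shocks: while tracking is unreliable,
    punishment is withheld to prevent false training.
    """
    if state.qc_flag is not QCFlag.ACCEPTED or not state.initialized:
        timers.pending_since_s = None
        return None
    p = state.level
    r = math.hypot(p[0], p[1])
    trig = rule.trigger
    satisfied = True
    if trig.in_quadrants is not None:
        physical = quadrant_of(
            p if r <= g.dish_radius_mm else (p[0] * g.dish_radius_mm / r,
                                             p[1] * g.dish_radius_mm / r),
            g,
        )
        cfg = _config_quadrant(physical, phase, phase_t_s)
        satisfied &= cfg in trig.in_quadrants
    if trig.edge_distance_lt is not None:
        satisfied &= (g.dish_radius_mm - r) < trig.edge_distance_lt
    if trig.center_distance_lt is not None:
        satisfied &= r < trig.center_distance_lt
    if trig.speed_lt is not None:
        satisfied &= mean_speed_mm_s < trig.speed_lt

    if not satisfied:
        timers.pending_since_s = None
        return None
    if timers.pending_since_s is None:
        timers.pending_since_s = t_s
    if t_s - timers.pending_since_s < rule.delay_s - 1e-9:
        return None
    if t_s - timers.last_onset_s < rule.refractory_s - 1e-9:
        return None
    timers.last_onset_s = t_s
    timers.pending_since_s = None
    return ShockCommand(
        current_mA=rule.current_mA,
        waveform_hz=rule.waveform_hz,
        duration_ms=quantize_duration(rule.duration_ms),
    )


def yoke(commands: Sequence[Optional[ShockCommand]], mode: str) -> List[Optional[ShockCommand]]:
    """Apply yoked-control pairing to per-channel stimulus commands.

    Channels pair as (0,1), (2,3), ...  In ``even_follow_odd`` mode
    each even channel receives the stimuli its odd partner's behaviour
    generated this tick (and vice versa for ``odd_follow_even``): the
    yoked animal's own position never influences what it receives.
    """
    if mode == "off":
        return list(commands)
    if mode not in ("even_follow_odd", "odd_follow_even"):
        raise ValueError(f"unknown yoked mode {mode!r}")
    if len(commands) % 2 != 0:
        raise ValueError("yoked control requires an even channel count")
    out = list(commands)
    for even in range(0, len(commands), 2):
        odd = even + 1
        if mode == "even_follow_odd":
            out[even] = commands[odd]
        else:
            out[odd] = commands[even]
    return out


@dataclass(frozen=True)
class TrialConfig:
    """Complete declarative description of a trial."""

    geometry: ArenaGeometry = ArenaGeometry()
    tracking: TrackingParams = TrackingParams()
    phases: Tuple[TrialPhase, ...] = ()
    tick_rate_hz: float = 10.0
    n_channels: int = 1
    yoked_mode: str = "off"

    def __post_init__(self) -> None:
        if not (0.0 < self.tick_rate_hz <= MAX_TICK_RATE_HZ):
            raise ValueError(f"tick_rate_hz must lie in (0, {MAX_TICK_RATE_HZ}]")
        if not self.phases:
            raise ValueError("trial needs at least one phase")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.yoked_mode not in ("off", "even_follow_odd", "odd_follow_even"):
            raise ValueError(f"unknown yoked mode {self.yoked_mode!r}")
        if self.yoked_mode != "off" and self.n_channels % 2 != 0:
            raise ValueError("yoked control requires an even channel count")

    @property
    def duration_s(self) -> float:
        return sum(p.duration_s for p in self.phases)


LOG_COLUMNS = (
    ["time_s", "channel", "x_mm", "y_mm", "speed_mm_s", "blob_area_px", "quadrant"]
    + [f"red_q{i}" for i in range(1, 5)]
    + [f"blue_q{i}" for i in range(1, 5)]
    + ["shock_on", "shock_mA", "qc_flag"]
)


class _SpeedWindow:
    """Trailing mean of the smoothed speed over a fixed window."""

    def __init__(self, n: int) -> None:
        from collections import deque

        self.values = deque(maxlen=max(n, 1))
        self.total = 0.0

    def push(self, v: float) -> float:
        if len(self.values) == self.values.maxlen:
            self.total -= self.values[0]
        self.values.append(v)
        self.total += v
        return self.total / len(self.values)


def run_trial(
    config: TrialConfig,
    frame_source,
    sink=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Execute the full observe-decide-actuate loop in simulated time.

    ``frame_source`` provides one observation per channel per tick via
    ``frame_source.step(channel, stimuli)``; an observation is either a
    grayscale frame (tracked through the vision pipeline) or a direct
    ``(x_mm, y_mm)`` position (smoothed only — used for scripted and
    fast closed-loop simulations).  Background models are initialized
    from ``frame_source.background_frames(channel)`` when frames are
    supplied.

    ``sink`` may be a file path or text handle; log rows stream to it
    as CSV while the full record is also returned as a DataFrame.
    """
    g = config.geometry
    tp = config.tracking
    dt = 1.0 / config.tick_rate_hz
    n_ticks = int(round(config.duration_s * config.tick_rate_hz))
    channels = list(range(config.n_channels))

    states = [TrackState(alpha=tp.alpha, beta=tp.beta) for _ in channels]
    models = [None] * config.n_channels
    timers: List[Dict[int, ChannelTimers]] = [dict() for _ in channels]
    speed_windows: List[Dict[int, _SpeedWindow]] = [dict() for _ in channels]
    last_stimuli = [
        {"red_levels": (0, 0, 0, 0), "blue_levels": (0, 0, 0, 0), "shock_on": False}
        for _ in channels
    ]

    # phase boundaries in ticks
    bounds = []
    acc = 0.0
    for ph in config.phases:
        acc += ph.duration_s
        bounds.append(acc)

    own_sink = None
    if isinstance(sink, (str, bytes)) or hasattr(sink, "__fspath__"):
        own_sink = open(sink, "w", newline="")
        sink = own_sink
    writer = csv.writer(sink) if sink is not None else None
    if writer is not None:
        writer.writerow(LOG_COLUMNS)

    rows = []
    try:
        for tick in range(n_ticks):
            t = tick * dt
            pi = 0
            while pi < len(bounds) - 1 and t >= bounds[pi] - 1e-9:
                pi += 1
            phase = config.phases[pi]
            phase_t = t - (bounds[pi] - phase.duration_s)
            red, blue = lighting_at(phase, phase_t)

            commands: List[Optional[ShockCommand]] = []
            observations = []
            for c in channels:
                obs = frame_source.step(c, last_stimuli[c])
                observations.append(obs)
                if isinstance(obs, np.ndarray):
                    if models[c] is None:
                        bg = frame_source.background_frames(c)
                        models[c] = init_background(bg)
                    states[c], models[c], blob = track_frame(obs, models[c], states[c], tp, g)
                    observations[-1] = blob
                else:
                    # direct position: treat as an accepted raw measurement
                    from .tracking import smooth

                    states[c] = smooth(states[c], (float(obs[0]), float(obs[1])))
                    observations[-1] = None

                speed = states[c].speed_mm_per_tick() * config.tick_rate_hz
                cmd: Optional[ShockCommand] = None
                for ri, rule in enumerate(phase.shock_rules):
                    tm = timers[c].setdefault((pi, ri), ChannelTimers())
                    win = speed_windows[c].setdefault(
                        (pi, ri), _SpeedWindow(int(round(rule.trigger.window_s / dt)))
                    )
                    mean_speed = win.push(speed)
                    cmd = evaluate_shock(
                        states[c], rule, t, tm, phase, phase_t, g, mean_speed
                    ) or cmd
                commands.append(cmd)

            commands = yoke(commands, config.yoked_mode)

            for c in channels:
                st = states[c]
                cmd = commands[c]
                level = st.level if st.initialized else (math.nan, math.nan)
                if st.initialized and st.qc_flag is QCFlag.ACCEPTED:
                    r = math.hypot(level[0], level[1])
                    pq = quadrant_of(
                        level
                        if r <= g.dish_radius_mm
                        else (level[0] * g.dish_radius_mm / r, level[1] * g.dish_radius_mm / r),
                        g,
                    )
                    quad = pq.name
                else:
                    quad = ""
                speed = st.speed_mm_per_tick() * config.tick_rate_hz if st.initialized else math.nan
                blob = observations[c]
                row = [
                    f"{t:.3f}",
                    c,
                    f"{level[0]:.3f}" if st.initialized else "",
                    f"{level[1]:.3f}" if st.initialized else "",
                    f"{speed:.3f}" if st.initialized else "",
                    blob.area_px if blob is not None else 0,
                    quad,
                    *red,
                    *blue,
                    int(cmd is not None),
                    f"{cmd.current_mA:.1f}" if cmd is not None else "0.0",
                    st.qc_flag.value,
                ]
                if writer is not None:
                    writer.writerow(row)
                rows.append(row)
                last_stimuli[c] = {
                    "red_levels": red,
                    "blue_levels": blue,
                    "shock_on": cmd is not None,
                }
    finally:
        if own_sink is not None:
            own_sink.close()

    df = pd.DataFrame(rows, columns=LOG_COLUMNS)
    for col in ("time_s", "x_mm", "y_mm", "speed_mm_s", "shock_mA"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in (
        ["channel", "blob_area_px", "shock_on"]
        + [f"red_q{i}" for i in range(1, 5)]
        + [f"blue_q{i}" for i in range(1, 5)]
    ):
        df[col] = pd.to_numeric(df[col]).astype(int)
    return df
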