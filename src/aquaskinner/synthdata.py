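"""Synthetic arena and animal: ground-truth fixtures for the whole stack.

Two generators live here.  The *behavioral agent* is a stochastic
point-animal with a configurable repertoire — persistent random-walk
locomotion, negative phototaxis down the blue-light gradient,
thigmotaxis toward the wall, an escape burst on shock, and an optional
conditioned blue/red association that accumulates with shock pairings.
The *renderer* draws the dish the camera would see through its red
filter: a dark elongated animal on a brighter background, a radial
edge shadow, slow background drift from meniscus microevaporation,
sensor noise and occasional bright bubbles.  Blue stimulus light never
reaches the sensor, so rendered frames are byte-identical whatever the
blue levels are.

The agent is a test harness standing in for animals, not a biological
model; its parameters are chosen to mimic the qualitative repertoire of
small aquatic animals in a 60 mm dish (cruise speeds of a few mm/s,
escape bursts an order of magnitude faster, strong wall affinity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .arena import ArenaGeometry, OutOfArenaError, mm_to_px

__all__ = [
    "AgentParams",
    "AgentState",
    "RenderParams",
    "step_agent",
    "render_frame",
    "empty_frame",
    "ScriptedTrajectory",
    "SimulationSource",
    "ScriptedSource",
    "run_tracking_fixture",
]


@dataclass(frozen=True)
class AgentParams:
    """Behavioral repertoire of the synthetic animal.

    ``photophobia_gain`` and ``conditioning_rate`` both act through the
    normalized blue-intensity field (quadrant levels / 10, interpolated
    across sector boundaries): photophobia drives the animal *down*
    the gradient innately, while each shock received adjusts a
    conditioned drive along the gradient — shocks experienced under low
    blue push the association toward blue-seeking, shocks under bright
    blue toward blue-avoidance.  That single scalar memory is what lets
    a trained agent keep a preference after punishment stops.
    """

    base_speed_mm_s: float = 2.0
    heading_persistence: float = 0.8
    turn_noise_deg: float = 25.0
    photophobia_gain: float = 0.0  # mm^2/s against the normalized blue gradient
    thigmotaxis_gain: float = 0.0  # mm/s outward radial drift
    burst_speed_mm_s: float = 25.0
    burst_duration_s: float = 1.5
    pause_prob: float = 0.0
    conditioning_rate: float = 0.0  # conditioned-drive increment per shock
    conditioning_max: float = 80.0
    wall_margin_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.base_speed_mm_s < 0 or self.burst_speed_mm_s < 0:
            raise ValueError("speeds must be non-negative")
        if not (0.0 <= self.heading_persistence < 1.0):
            raise ValueError("heading_persistence must lie in [0, 1)")
        if not (0.0 <= self.pause_prob <= 1.0):
            raise ValueError("pause_prob must lie in [0, 1]")


@dataclass
class AgentState:
    x_mm: float = 0.0
    y_mm: float = 0.0
    heading_rad: float = 0.0
    burst_remaining_s: float = 0.0
    conditioned_blue_drive: float = 0.0  # mm^2/s along the blue gradient


def _blue_field(
    p: Tuple[float, float], blue_levels: Sequence[int], g: ArenaGeometry
) -> Tuple[float, Tuple[float, float]]:
    """Normalized blue intensity at ``p`` and its spatial gradient.

    Quadrant levels are interpolated linearly in angle between sector
    centres, giving a continuous field whose gradient is tangential at
    sector boundaries — the direction an animal crossing between a lit
    and a dark quadrant actually experiences.
    """
    x, y = p
    r = math.hypot(x, y)
    theta = math.atan2(y, x)
    centre0 = math.radians(g.divider_angle_deg + 45.0)
    u = (theta - centre0) / (math.pi / 2.0)  # quadrant-centre units
    k = math.floor(u)
    frac = u - k
    lo = blue_levels[k % 4] / 10.0
    hi = blue_levels[(k + 1) % 4] / 10.0
    b = lo + (hi - lo) * frac
    dbdtheta = (hi - lo) / (math.pi / 2.0)
    r_eff = max(r, 2.0)
    gmag = dbdtheta / r_eff
    return b, (-gmag * math.sin(theta), gmag * math.cos(theta))


def step_agent(
    state: AgentState,
    params: AgentParams,
    stimuli: Dict,
    g: ArenaGeometry,
    rng: np.random.Generator,
    dt_s: float,
) -> AgentState:
    """Advance the agent by one tick.

    ``stimuli`` carries ``blue_levels`` (per physical quadrant) and
    ``shock_on``; the agent reacts to the commanded light levels (the
    animals see blue, the camera does not).  Position reflects at the
    wall so the animal can never leave the dish.  Given the same state,
    parameters, stimuli and PRNG stream the step is fully deterministic.
    """
    blue = stimuli.get("blue_levels", (0, 0, 0, 0))
    shock = bool(stimuli.get("shock_on", False))

    s = AgentState(**vars(state))
    b_here, grad_b = _blue_field((s.x_mm, s.y_mm), blue, g)

    if shock:
        s.burst_remaining_s = params.burst_duration_s
        if params.conditioning_rate > 0.0:
            s.conditioned_blue_drive = float(
                np.clip(
                    s.conditioned_blue_drive
                    + params.conditioning_rate * (1.0 - 2.0 * b_here),
                    -params.conditioning_max,
                    params.conditioning_max,
                )
            )
        s.heading_rad += rng.normal(0.0, math.pi / 2.0)

    bursting = s.burst_remaining_s > 0.0
    speed = params.burst_speed_mm_s if bursting else params.base_speed_mm_s
    noise_scale = math.radians(params.turn_noise_deg) * (1.0 - params.heading_persistence)
    s.heading_rad += rng.normal(0.0, noise_scale)

    paused = (not bursting) and params.pause_prob > 0.0 and rng.random() < params.pause_prob

    vx = speed * math.cos(s.heading_rad)
    vy = speed * math.sin(s.heading_rad)
    gain = s.conditioned_blue_drive - params.photophobia_gain
    vx += gain * grad_b[0]
    vy += gain * grad_b[1]
    r = math.hypot(s.x_mm, s.y_mm)
    if params.thigmotaxis_gain != 0.0 and r > 1e-9:
        vx += params.thigmotaxis_gain * s.x_mm / r
        vy += params.thigmotaxis_gain * s.y_mm / r

    if not paused:
        s.x_mm += vx * dt_s
        s.y_mm += vy * dt_s
        rb = g.dish_radius_mm - params.wall_margin_mm
        rr = math.hypot(s.x_mm, s.y_mm)
        if rr > rb:
            # fold the radial overshoot back inside and reflect the
            # velocity specularly off the wall, so tangential motion is
            # preserved and the animal glides along the boundary
            nx, ny = s.x_mm / rr, s.y_mm / rr
            scale = max(2.0 * rb - rr, 0.0) / rr
            s.x_mm *= scale
            s.y_mm *= scale
            vn = vx * nx + vy * ny
            rvx, rvy = vx - 2.0 * vn * nx, vy - 2.0 * vn * ny
            if rvx != 0.0 or rvy != 0.0:
                s.heading_rad = math.atan2(rvy, rvx)
        elif vx != 0.0 or vy != 0.0:
            s.heading_rad = math.atan2(vy, vx)

    if bursting:
        s.burst_remaining_s = max(0.0, s.burst_remaining_s - dt_s)
    return s


# ---------------------------------------------------------------------------
# renderer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RenderParams:
    """Optical model of one channel as seen through the red filter."""

    animal_axes_mm: Tuple[float, float] = (3.0, 1.0)  # ellipse semi-axes
    orientation_follows_heading: bool = True
    animal_intensity: float = 100.0
    background_intensity: float = 180.0
    outside_intensity: float = 60.0
    edge_shadow_gain: float = 0.25
    edge_shadow_width_mm: float = 4.0
    meniscus_drift: float = 0.0  # gray levels per 1000 ticks (signed)
    sensor_noise_sd: float = 2.0
    bubble_rate: float = 0.0  # per-frame probability of one bright bubble
    bubble_radius_px: int = 8

    def __post_init__(self) -> None:
        if not (0.0 <= self.animal_intensity <= 255.0 and 0.0 <= self.background_intensity <= 255.0):
            raise ValueError("intensities must fit the 8-bit range")


@lru_cache(maxsize=8)
def _static_scene(rp: RenderParams, g: ArenaGeometry):
    """Cached noise-free empty-dish image and coordinate grids (mm)."""
    yy, xx = np.mgrid[0 : g.image_height_px, 0 : g.image_width_px]
    x = (xx - g.center_px[0]) * g.mm_per_px
    y = -(yy - g.center_px[1]) * g.mm_per_px
    r = np.hypot(x, y)
    inside = r < g.dish_radius_mm
    w = rp.edge_shadow_width_mm
    s = np.clip((r - (g.dish_radius_mm - w)) / w, 0.0, 1.0)
    shadow = 1.0 - rp.edge_shadow_gain * s * s
    base = np.where(inside, rp.background_intensity * shadow, rp.outside_intensity)
    return base, x, y, shadow, inside


def empty_frame(
    rp: RenderParams,
    g: ArenaGeometry,
    tick: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render the empty dish at a given tick (drift applied, no animal)."""
    base, _, _, _, inside = _static_scene(rp, g)
    img = base + rp.meniscus_drift * tick / 1000.0 * inside
    if rng is not None and rp.sensor_noise_sd > 0:
        img = img + rng.normal(0.0, rp.sensor_noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def render_frame(
    pos_mm: Tuple[float, float],
    heading_rad: float,
    rp: RenderParams,
    g: ArenaGeometry,
    tick: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, Tuple[float, float]]:
    """Render one frame; returns ``(uint8 frame, ground-truth centroid px)``.

    The animal is a dark ellipse aligned with its heading, multiplied by
    the same edge-shadow profile as the background so that near-wall
    contrast shrinks realistically.  The rendered image depends only on
    position, heading and tick — never on blue-light state.
    """
    if math.hypot(*pos_mm) > g.dish_radius_mm:
        raise OutOfArenaError(f"animal position {pos_mm} outside dish")
    base, x, y, shadow, inside = _static_scene(rp, g)
    img = base + rp.meniscus_drift * tick / 1000.0 * inside

    a, b = rp.animal_axes_mm
    th = heading_rad if rp.orientation_follows_heading else 0.0
    dx = x - pos_mm[0]
    dy = y - pos_mm[1]
    c, s = math.cos(th), math.sin(th)
    u = (dx * c + dy * s) / a
    v = (-dx * s + dy * c) / b
    ellipse = (u * u + v * v <= 1.0) & inside
    img = np.where(ellipse, rp.animal_intensity * shadow, img)

    if rng is not None:
        if rp.bubble_rate > 0.0 and rng.random() < rp.bubble_rate:
            ang = rng.uniform(0.0, 2.0 * math.pi)
            rad = rng.uniform(0.0, g.dish_radius_mm - 5.0)
            bx, by = rad * math.cos(ang), rad * math.sin(ang)
            br = rp.bubble_radius_px * g.mm_per_px
            bubble = ((x - bx) ** 2 + (y - by) ** 2 <= br * br) & inside
            img = np.where(bubble, 250.0, img)
        if rp.sensor_noise_sd > 0:
            img = img + rng.normal(0.0, rp.sensor_noise_sd, img.shape)

    frame = np.clip(img, 0, 255).astype(np.uint8)
    return frame, mm_to_px(pos_mm, g)


# ---------------------------------------------------------------------------
# scripted trajectories
# ---------------------------------------------------------------------------


class ScriptedTrajectory:
    """Piecewise-linear deterministic position function of time.

    Used for exact-count controller tests where the ground truth must
    be trivial to reason about (shock-event arithmetic, rotation
    following, edge circling).
    """

    def __init__(self, waypoints: Sequence[Tuple[float, Tuple[float, float]]],
                 g: Optional[ArenaGeometry] = None) -> None:
        if not waypoints:
            raise ValueError("need at least one waypoint")
        times = [t for t, _ in waypoints]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("waypoints must be strictly time-sorted")
        if g is not None:
            for t, p in waypoints:
                if math.hypot(p[0], p[1]) > g.dish_radius_mm + 1e-9:
                    raise OutOfArenaError(f"waypoint at t={t} outside dish: {p}")
        self.times = times
        self.points = [p for _, p in waypoints]

    def __call__(self, t_s: float) -> Tuple[float, float]:
        ts, ps = self.times, self.points
        if t_s <= ts[0]:
            return ps[0]
        if t_s >= ts[-1]:
            return ps[-1]
        import bisect

        i = bisect.bisect_right(ts, t_s) - 1
        f = (t_s - ts[i]) / (ts[i + 1] - ts[i])
        return (
            ps[i][0] + f * (ps[i + 1][0] - ps[i][0]),
            ps[i][1] + f * (ps[i + 1][1] - ps[i][1]),
        )

    def heading(self, t_s: float, eps: float = 1e-3) -> float:
        p0 = self(t_s)
        p1 = self(t_s + eps)
        if p0 == p1:
            return 0.0
        return math.atan2(p1[1] - p0[1], p1[0] - p0[0])


def circle_trajectory(radius_mm: float, speed_mm_s: float, duration_s: float,
                      n_points: int = 720) -> ScriptedTrajectory:
    """Constant-speed circular path, a standard tracking fixture."""
    omega = speed_mm_s / radius_mm
    pts = []
    for i in range(n_points + 1):
        t = duration_s * i / n_points
        pts.append((t, (radius_mm * math.cos(omega * t), radius_mm * math.sin(omega * t))))
    return ScriptedTrajectory(pts)


# ---------------------------------------------------------------------------
# channel sources for the trial loop
# ---------------------------------------------------------------------------


def _channel_rng(seed: int, channel: int, stream: int = 0) -> np.random.Generator:
    """One independent PRNG stream per channel, keyed by (seed, channel)
    so that adding or reordering channels never perturbs another
    channel's trajectory."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(channel, stream))
    )


class SimulationSource:
    """Closed-loop frame/position source backed by behavioral agents.

    ``emit='frames'`` renders full camera frames (exercising the vision
    pipeline); ``emit='positions'`` hands ground-truth positions
    straight to the controller, which is orders of magnitude faster and
    appropriate when the question under study is the control loop, not
    the tracker.
    """

    def __init__(
        self,
        g: ArenaGeometry,
        agent_params: AgentParams,
        render_params: Optional[RenderParams] = None,
        n_channels: int = 1,
        seed: int = 0,
        tick_rate_hz: float = 10.0,
        emit: str = "positions",
        initial_positions: Optional[Sequence[Tuple[float, float]]] = None,
    ) -> None:
        if emit not in ("positions", "frames"):
            raise ValueError("emit must be 'positions' or 'frames'")
        if emit == "frames" and render_params is None:
            render_params = RenderParams()
        self.g = g
        self.params = agent_params
        self.render_params = render_params
        self.emit = emit
        self.seed = seed
        self.dt = 1.0 / tick_rate_hz
        self.rngs = [_channel_rng(seed, c) for c in range(n_channels)]
        self.states = []
        for c in range(n_channels):
            if initial_positions is not None:
                x0, y0 = initial_positions[c]
            else:
                ang = self.rngs[c].uniform(0.0, 2.0 * math.pi)
                rad = math.sqrt(self.rngs[c].uniform(0.0, 1.0)) * (g.dish_radius_mm - 5.0)
                x0, y0 = rad * math.cos(ang), rad * math.sin(ang)
            self.states.append(
                AgentState(x_mm=x0, y_mm=y0,
                           heading_rad=self.rngs[c].uniform(0.0, 2.0 * math.pi))
            )
        self.ticks = [0] * n_channels
        self.truth: List[List[Tuple[float, float]]] = [[] for _ in range(n_channels)]

    def step(self, channel: int, stimuli: Dict):
        st = step_agent(self.states[channel], self.params, stimuli, self.g,
                        self.rngs[channel], self.dt)
        self.states[channel] = st
        self.ticks[channel] += 1
        self.truth[channel].append((st.x_mm, st.y_mm))
        if self.emit == "positions":
            return (st.x_mm, st.y_mm)
        frame, _ = render_frame((st.x_mm, st.y_mm), st.heading_rad, self.render_params,
                                self.g, self.ticks[channel], self.rngs[channel])
        return frame

    def background_frames(self, channel: int, n: int = 5):
        rng = _channel_rng(self.seed, channel, stream=1)
        return [empty_frame(self.render_params, self.g, 0, rng) for _ in range(n)]


class ScriptedSource:
    """Deterministic source replaying scripted trajectories."""

    def __init__(
        self,
        trajectories: Sequence[Callable[[float], Tuple[float, float]]],
        tick_rate_hz: float = 10.0,
    ) -> None:
        self.trajectories = list(trajectories)
        self.dt = 1.0 / tick_rate_hz
        self.ticks = [0] * len(self.trajectories)

    def step(self, channel: int, stimuli: Dict):
        t = self.ticks[channel] * self.dt
        self.ticks[channel] += 1
        return self.trajectories[channel](t)


# ---------------------------------------------------------------------------
# tracking fixture harness
# ---------------------------------------------------------------------------


def run_tracking_fixture(
    trajectory: ScriptedTrajectory,
    rp: RenderParams,
    tp,
    g: ArenaGeometry,
    n_frames: int,
    tick_rate_hz: float = 10.0,
    seed: int = 0,
    heal: bool = True,
    n_background: int = 5,
) -> Dict:
    """Render a scripted trajectory and run the tracker over it.

    Returns accepted fraction, RMS raw-centroid error (px, over
    accepted frames) and the per-frame records — the standard way the
    test suite measures tracker performance against ground truth.
    """
    from .tracking import QCFlag, TrackState, init_background, track_frame

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    bg_frames = [empty_frame(rp, g, 0, rng) for _ in range(n_background)]
    model = init_background(bg_frames)
    state = TrackState(alpha=tp.alpha, beta=tp.beta)
    dt = 1.0 / tick_rate_hz

    accepted = 0
    sq_err = []
    records = []
    for i in range(n_frames):
        t = i * dt
        pos = trajectory(t)
        frame, truth_px = render_frame(pos, trajectory.heading(t), rp, g, i, rng)
        state, model, blob = track_frame(frame, model, state, tp, g, heal=heal)
        ok = state.qc_flag is QCFlag.ACCEPTED
        if ok:
            accepted += 1
            err = math.hypot(blob.centroid_px[0] - truth_px[0],
                             blob.centroid_px[1] - truth_px[1])
            sq_err.append(err * err)
        records.append((t, pos, state, blob))
    return {
        "accepted_fraction": accepted / n_frames,
        "rms_error_px": math.sqrt(sum(sq_err) / len(sq_err)) if sq_err else math.inf,
        "records": records,
    }
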