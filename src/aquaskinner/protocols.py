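"""Ready-made training protocols and closed-loop demonstrations.

The centrepiece is the tadpole red-aversion protocol: a 30 min initial
preference test under half-blue/half-red lighting rotating 90 degrees
clockwise every 10 min, four 30 min training sessions in which the red
half is punished (1.2 mA, 10 s refractory), 90 min all-blue rests
between sessions, and a final unpunished 30 min preference test.  Run
against the synthetic conditioned agent it demonstrates the full
closed loop: within-session escape from the punished half and a
persistent post-training preference for blue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .analysis import default_region_label
from .config import fig_protocol_config
from .controller import run_trial
from .synthdata import AgentParams, SimulationSource

__all__ = ["conditioned_tadpole_params", "run_red_aversion_demo", "RedAversionResult"]


def conditioned_tadpole_params() -> AgentParams:
    """Agent mimicking a young tadpole's repertoire in this assay:
    continuous cruising, shock-escape bursts fast enough to circle the
    dish in a few seconds, mild wall affinity, no innate blue
    photophobia, and a shock-conditioned blue/red association."""
    return AgentParams(
        base_speed_mm_s=5.0,
        heading_persistence=0.85,
        turn_noise_deg=30.0,
        photophobia_gain=0.0,
        thigmotaxis_gain=1.0,
        burst_speed_mm_s=30.0,
        burst_duration_s=1.5,
        pause_prob=0.0,
        conditioning_rate=15.0,
        conditioning_max=60.0,
    )


def _in_red_half(df: pd.DataFrame) -> pd.Series:
    """Per-tick flag: accepted and under red-dominant lighting."""
    quads = df["quadrant"].str[1:]
    red = pd.Series(False, index=df.index)
    for q in range(1, 5):
        m = (quads == str(q)) & (df["qc_flag"] == "accepted")
        if m.any():
            red[m] = [
                default_region_label(r, b) == "red"
                for r, b in zip(df.loc[m, f"red_q{q}"], df.loc[m, f"blue_q{q}"])
            ]
    return red


@dataclass
class RedAversionResult:
    record: pd.DataFrame
    #: red-half occupancy over the first 30 s of the first training session
    first30_red_fraction: float
    #: red-half occupancy over the last third of each training session
    last_third_red_fraction: List[float]
    #: shock count per training session
    shocks_per_session: List[int]
    #: blue-half occupancy per 5-min bin of the post-test
    posttest_blue_by_bin: List[float]


def run_red_aversion_demo(
    seed: int = 0,
    tick_rate_hz: float = 10.0,
    rest_s: float = 5400.0,
    agent: AgentParams = None,
    channel: int = 0,
    n_channels: int = 1,
) -> RedAversionResult:
    """Run the red-aversion protocol closed-loop on the synthetic agent.

    The agent starts at the dish centre (as a freshly loaded animal
    would) and the simulation hands ground-truth positions straight to
    the controller, which is the appropriate mode for studying the
    control loop at protocol scale.
    """
    agent = agent or conditioned_tadpole_params()
    cfg = fig_protocol_config(tick_rate_hz=tick_rate_hz, n_channels=n_channels,
                              rest_s=rest_s)
    source = SimulationSource(
        cfg.geometry,
        agent,
        n_channels=n_channels,
        seed=seed,
        tick_rate_hz=tick_rate_hz,
        initial_positions=[(0.0, 0.0)] * n_channels,
    )
    df = run_trial(cfg, source)
    rec = df[df["channel"] == channel].reset_index(drop=True)
    in_red = _in_red_half(rec)
    acc = rec["qc_flag"] == "accepted"
    t = rec["time_s"]

    session_s = 1800.0
    starts = [session_s + i * (session_s + rest_s) for i in range(4)]

    def red_frac(lo: float, hi: float) -> float:
        m = acc & (t >= lo) & (t < hi)
        return float(in_red[m].mean()) if m.any() else 0.0

    first30 = red_frac(starts[0], starts[0] + 30.0)
    last_thirds = [red_frac(s + 2 * session_s / 3, s + session_s) for s in starts]
    shocks = [
        int(rec["shock_on"][(t >= s) & (t < s + session_s)].sum()) for s in starts
    ]
    post_start = starts[3] + session_s + rest_s
    post_bins = [
        1.0 - red_frac(post_start + k * 300.0, post_start + (k + 1) * 300.0)
        for k in range(6)
    ]
    return RedAversionResult(
        record=df,
        first30_red_fraction=first30,
        last_third_red_fraction=last_thirds,
        shocks_per_session=shocks,
        posttest_blue_by_bin=post_bins,
    )
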