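"""YAML trial configuration.

A trial file is one YAML document with sections ``geometry``,
``tracking``, ``phases`` (a list), ``channels`` and ``yoked_mode`` —
the GUI fields of the original apparatus expressed as data.  Example::

    tick_rate_hz: 10
    channels: 1
    yoked_mode: off
    geometry:
      dish_radius_mm: 30.0
      mm_per_px: 0.25
      center_px: [119.5, 119.5]
      divider_angle_deg: 0
      electrodes: {n: 6, arc_deg: 10}
    tracking:
      expected_area_px: 150
      dq_threshold: 0.2
      alpha: 0.5
      beta: 0.3
    phases:
      - name: pretest
        duration_s: 1800
        light:
          red:  [2, 2, 2, 2]
          blue: [8, 8, 0, 0]
        rotation: {angle_deg: 90, interval_s: 600}
      - name: training
        duration_s: 1800
        light:
          red:  [2, 2, 2, 2]
          blue: [8, 8, 0, 0]
        rotation: {angle_deg: 90, interval_s: 600}
        shock_rules:
          - in_quadrants: [Q3, Q4]
            current_mA: 1.2
            waveform_hz: 100
            duration_ms: 96
            refractory_s: 10

Light levels must be integers 0–10 (ten even steps above off);
anything else is rejected at load time.
"""

from __future__ import annotations

from typing import Dict, Optional

import yaml

from .arena import ArenaGeometry, Quadrant
from .controller import (
    LightSpec,
    RotationSpec,
    ShockRule,
    ShockTrigger,
    TrialConfig,
    TrialPhase,
)
from .tracking import TrackingParams

__all__ = ["load_trial_config", "parse_trial_config", "fig_protocol_config"]


def _geometry(d: Optional[Dict]) -> ArenaGeometry:
    d = dict(d or {})
    el = d.pop("electrodes", None) or {}
    kwargs = {}
    for key in ("dish_radius_mm", "mm_per_px", "divider_angle_deg",
                "image_width_px", "image_height_px"):
        if key in d:
            kwargs[key] = d[key]
    if "center_px" in d:
        kwargs["center_px"] = tuple(d["center_px"])
    if "n" in el:
        kwargs["n_electrodes"] = int(el["n"])
    if "arc_deg" in el:
        kwargs["electrode_arc_deg"] = float(el["arc_deg"])
    return ArenaGeometry(**kwargs)


def _tracking(d: Optional[Dict]) -> TrackingParams:
    d = dict(d or {})
    if "area_bounds" in d:
        d["area_bounds"] = tuple(d["area_bounds"])
    return TrackingParams(**d)


def _phase(d: Dict) -> TrialPhase:
    light = d.get("light", {})
    spec = LightSpec(
        red=tuple(light.get("red", (2, 2, 2, 2))),
        blue=tuple(light.get("blue", (0, 0, 0, 0))),
    )
    rotation = None
    if d.get("rotation"):
        rotation = RotationSpec(
            angle_deg=int(d["rotation"].get("angle_deg", 90)),
            interval_s=float(d["rotation"].get("interval_s", 600.0)),
        )
    rules = []
    for rd in d.get("shock_rules", []) or []:
        rd = dict(rd)
        trig = ShockTrigger(
            in_quadrants=frozenset(Quadrant[q] for q in rd.pop("in_quadrants"))
            if "in_quadrants" in rd
            else None,
            edge_distance_lt=rd.pop("edge_distance_lt", None),
            center_distance_lt=rd.pop("center_distance_lt", None),
            speed_lt=rd.pop("speed_lt", None),
            window_s=rd.pop("window_s", 5.0),
        )
        rules.append(ShockRule(trigger=trig, **rd))
    return TrialPhase(
        name=str(d.get("name", "phase")),
        duration_s=float(d["duration_s"]),
        light_spec=spec,
        rotation=rotation,
        shock_rules=tuple(rules),
    )


def parse_trial_config(doc: Dict) -> TrialConfig:
    """Build a validated :class:`TrialConfig` from a parsed YAML mapping."""
    phases = tuple(_phase(p) for p in doc.get("phases", []))
    return TrialConfig(
        geometry=_geometry(doc.get("geometry")),
        tracking=_tracking(doc.get("tracking")),
        phases=phases,
        tick_rate_hz=float(doc.get("tick_rate_hz", 10.0)),
        n_channels=int(doc.get("channels", 1)),
        yoked_mode=str(doc.get("yoked_mode", "off")),
    )


def load_trial_config(path) -> TrialConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("trial config must be a YAML mapping")
    return parse_trial_config(doc)


def fig_protocol_config(
    tick_rate_hz: float = 10.0,
    n_channels: int = 1,
    rest_s: float = 5400.0,
    shock_mA: float = 1.2,
) -> TrialConfig:
    """The tadpole red-aversion protocol as a ready-made config.

    30 min initial preference (half the dish under bright blue, half
    under dim red, rotating 90 deg clockwise every 10 min), then four
    30 min training sessions in which occupancy of the red half is
    punished with a 1.2 mA shock (10 s refractory), separated by
    all-blue rest periods, then a 30 min unpunished post-test identical
    to the pre-test.  ``rest_s`` defaults to the full 90 min rests; it
    can be shortened for desk-scale runs.
    """
    test_light = LightSpec(red=(2, 2, 2, 2), blue=(8, 8, 0, 0))
    rest_light = LightSpec(red=(2, 2, 2, 2), blue=(8, 8, 8, 8))
    rot = RotationSpec(angle_deg=90, interval_s=600.0)
    red_half_rule = ShockRule(
        trigger=ShockTrigger(in_quadrants=frozenset({Quadrant.Q3, Quadrant.Q4})),
        current_mA=shock_mA,
        waveform_hz=100.0,
        duration_ms=96,
        delay_s=0.0,
        refractory_s=10.0,
    )
    phases = [TrialPhase("pretest", 1800.0, test_light, rot)]
    for i in range(4):
        phases.append(
            TrialPhase(f"training{i + 1}", 1800.0, test_light, rot, (red_half_rule,))
        )
        phases.append(TrialPhase(f"rest{i + 1}", rest_s, rest_light))
    phases.append(TrialPhase("posttest", 1800.0, test_light, rot))
    return TrialConfig(
        phases=tuple(phases), tick_rate_hz=tick_rate_hz, n_channels=n_channels
    )
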