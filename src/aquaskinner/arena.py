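"""Dish geometry, coordinate conventions and calibration.

Two coordinate frames are used throughout the package:

* **image coordinates** — 0-based pixel indices, ``x`` to the right and
  ``y`` downward, as delivered by the camera;
* **dish coordinates** — millimetres, origin at the dish centre, ``x``
  to the right and ``y`` **up** (right-handed), shared by the tracker,
  the controller, the field solver and the analytics.

The arena is a standard 60 mm petri dish viewed from below, divided into
four lighting quadrants by two perpendicular vanes and ringed by six
electrode contacts on the wall of the holding insert.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Tuple

import numpy as np

__all__ = [
    "ArenaGeometry",
    "Quadrant",
    "OutOfArenaError",
    "px_to_mm",
    "mm_to_px",
    "quadrant_of",
    "edge_distance",
    "center_distance",
    "quadrant_label_image",
    "dish_mask",
]

#: slack allowed on the dish-boundary containment check, mm
ARENA_TOL_MM = 1e-6


class OutOfArenaError(ValueError):
    """A dish-coordinate point lies outside the dish."""


class Quadrant(Enum):
    """The four lighting quadrants, counterclockwise from the divider axis."""

    Q1 = 0
    Q2 = 1
    Q3 = 2
    Q4 = 3

    def rotated(self, n: int = 1) -> "Quadrant":
        """Quadrant reached after rotating ``n`` sectors counterclockwise."""
        return Quadrant((self.value + n) % 4)


@dataclass(frozen=True)
class ArenaGeometry:
    """Calibration and layout of one channel's dish.

    Parameters
    ----------
    dish_radius_mm:
        Radius of the water surface; 30 mm for a standard 60x15 mm dish.
    image_width_px, image_height_px:
        Camera frame size.
    mm_per_px:
        Isotropic pixel pitch at the dish plane.
    center_px:
        Image coordinates of the dish centre (may be fractional).
    divider_angle_deg:
        Orientation of the two perpendicular quadrant vanes; 0 puts the
        vanes along the dish-coordinate axes.
    n_electrodes:
        Number of wall electrode contacts (6 in the physical insert).
    electrode_angles_deg:
        Angular position of each contact centre, degrees CCW from +x.
    electrode_arc_deg:
        Angular width of each contact; a hardware parameter that is not
        published, so it stays configurable (10 degrees by default).
    """

    dish_radius_mm: float = 30.0
    image_width_px: int = 240
    image_height_px: int = 240
    mm_per_px: float = 0.25
    center_px: Tuple[float, float] = (119.5, 119.5)
    divider_angle_deg: float = 0.0
    n_electrodes: int = 6
    electrode_angles_deg: Tuple[float, ...] = field(default=None)  # type: ignore[assignment]
    electrode_arc_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.dish_radius_mm <= 0:
            raise ValueError("dish_radius_mm must be positive")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.n_electrodes < 2:
            raise ValueError("need at least 2 electrodes")
        if self.electrode_angles_deg is None:
            angles = tuple(i * 360.0 / self.n_electrodes for i in range(self.n_electrodes))
            object.__setattr__(self, "electrode_angles_deg", angles)
        angles = self.electrode_angles_deg
        if len(angles) != self.n_electrodes:
            raise ValueError("electrode_angles_deg length must equal n_electrodes")
        if any(not (0.0 <= a < 360.0) for a in angles):
            raise ValueError("electrode angles must lie in [0, 360)")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValueError("electrode angles must be strictly increasing")
        if not (0.0 < self.electrode_arc_deg < 360.0 / self.n_electrodes):
            raise ValueError("electrode_arc_deg must be positive and leave gaps between contacts")

    @property
    def dish_diameter_mm(self) -> float:
        return 2.0 * self.dish_radius_mm


def _check_in_dish(p_mm: Tuple[float, float], g: ArenaGeometry) -> float:
    r = math.hypot(p_mm[0], p_mm[1])
    if r > g.dish_radius_mm + ARENA_TOL_MM:
        raise OutOfArenaError(
            f"point {p_mm} at r={r:.3f} mm lies outside the {g.dish_radius_mm} mm dish"
        )
    return r


def px_to_mm(p_px: Tuple[float, float], g: ArenaGeometry) -> Tuple[float, float]:
    """Map an image point to dish coordinates (mm, centre origin, y up)."""
    x = (p_px[0] - g.center_px[0]) * g.mm_per_px
    y = -(p_px[1] - g.center_px[1]) * g.mm_per_px
    return (x, y)


def mm_to_px(p_mm: Tuple[float, float], g: ArenaGeometry) -> Tuple[float, float]:
    """Inverse of :func:`px_to_mm`."""
    px = p_mm[0] / g.mm_per_px + g.center_px[0]
    py = -p_mm[1] / g.mm_per_px + g.center_px[1]
    return (px, py)


def quadrant_of(p_mm: Tuple[float, float], g: ArenaGeometry) -> Quadrant:
    """Quadrant containing a dish point.

    Sectors are half-open, ``[divider + k*90, divider + (k+1)*90)``
    degrees, so points exactly on a vane are assigned deterministically
    to the sector whose lower edge they sit on; the exact centre goes to
    Q1 by convention.
    """
    _check_in_dish(p_mm, g)
    if p_mm[0] == 0.0 and p_mm[1] == 0.0:
        return Quadrant.Q1
    ang = math.degrees(math.atan2(p_mm[1], p_mm[0]))
    rel = (ang - g.divider_angle_deg) % 360.0
    return Quadrant(int(rel // 90.0) % 4)


def center_distance(p_mm: Tuple[float, float], g: ArenaGeometry) -> float:
    """Distance from the dish centre, mm."""
    return _check_in_dish(p_mm, g)


def edge_distance(p_mm: Tuple[float, float], g: ArenaGeometry) -> float:
    """Distance from the dish wall, mm (0 at the wall, R at the centre)."""
    return max(0.0, g.dish_radius_mm - _check_in_dish(p_mm, g))


@lru_cache(maxsize=8)
def quadrant_label_image(g: ArenaGeometry) -> np.ndarray:
    """Per-pixel quadrant index (0..3) for a full camera frame.

    Every pixel is labelled by its angular sector, including pixels
    outside the dish (the corners belong to the nearest quadrant's
    region for background-healing purposes).
    """
    yy, xx = np.mgrid[0 : g.image_height_px, 0 : g.image_width_px]
    x = (xx - g.center_px[0]) * g.mm_per_px
    y = -(yy - g.center_px[1]) * g.mm_per_px
    rel = (np.degrees(np.arctan2(y, x)) - g.divider_angle_deg) % 360.0
    return (rel // 90.0).astype(np.int8) % 4


@lru_cache(maxsize=8)
def dish_mask(g: ArenaGeometry) -> np.ndarray:
    """Boolean image mask of pixels whose centres lie inside the dish."""
    yy, xx = np.mgrid[0 : g.image_height_px, 0 : g.image_width_px]
    x = (xx - g.center_px[0]) * g.mm_per_px
    y = (yy - g.center_px[1]) * g.mm_per_px
    return x * x + y * y < g.dish_radius_mm**2
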