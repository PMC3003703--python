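"""Three-stage machine-vision tracker.

Stage 1 turns a raw camera frame into candidate blobs: background
subtraction against a self-healing background model, an area-aware
histogram stretch, a statistics-based binary threshold, and connected
component selection.  Stage 2 is frame quality control (jump, area and
no-blob tests).  Stage 3 converts the accepted centroid to dish
coordinates and runs Holt double-exponential smoothing to maintain the
best estimate of position and vector velocity.

The camera watches through a 632 nm narrowband red filter, so frames
are single-channel grayscale and are unaffected by the blue stimulus
lights; colour input is reduced to luminance before processing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence, Set, Tuple

import numpy as np
from skimage import measure

from .arena import (
    ArenaGeometry,
    Quadrant,
    dish_mask,
    px_to_mm,
    quadrant_label_image,
    quadrant_of,
)

__all__ = [
    "BackgroundModel",
    "Blob",
    "QCFlag",
    "TrackState",
    "TrackingParams",
    "init_background",
    "heal_background",
    "subtract_and_stretch",
    "binarize",
    "select_blobs",
    "qc_frame",
    "smooth",
    "track_frame",
]


class QCFlag(Enum):
    ACCEPTED = "accepted"
    REJECTED_JUMP = "rejected_jump"
    REJECTED_AREA = "rejected_area"
    NO_BLOB = "no_blob"


@dataclass
class BackgroundModel:
    """Reference image of the empty dish, healed quadrant by quadrant.

    ``background`` is kept in float64 so fractional healing updates do
    not quantize away; ``per_quadrant_age`` counts ticks since each
    quadrant's region was last refreshed.
    """

    background: np.ndarray
    per_quadrant_age: np.ndarray
    update_weight: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.update_weight <= 1.0):
            raise ValueError("update_weight must be in (0, 1]")


@dataclass(frozen=True)
class Blob:
    """One connected bright component of the thresholded image."""

    centroid_px: Tuple[float, float]  # (x, y) image coordinates
    area_px: int
    bbox: Tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    perimeter_px: float


@dataclass(frozen=True)
class TrackState:
    """Holt level/trend estimate of one animal's position.

    ``level`` is the smoothed dish position (mm), ``trend`` the velocity
    in mm per tick.  While a frame is rejected the estimate coasts:
    level and trend carry forward unchanged and only the flag updates.
    """

    level: Optional[Tuple[float, float]] = None
    trend: Tuple[float, float] = (0.0, 0.0)
    last_raw: Optional[Tuple[float, float]] = None
    qc_flag: QCFlag = QCFlag.NO_BLOB
    alpha: float = 0.5
    beta: float = 0.3

    @property
    def initialized(self) -> bool:
        return self.level is not None

    def speed_mm_per_tick(self) -> float:
        return math.hypot(self.trend[0], self.trend[1])


@dataclass(frozen=True)
class TrackingParams:
    """Tunables of the per-frame pipeline; defaults suit a ~6 mm animal
    imaged at 0.25 mm/px."""

    expected_area_px: int = 150
    stretch_headroom: float = 2.0
    noise_k: float = 3.0
    min_area_px: int = 50
    area_bounds: Tuple[int, int] = (60, 500)
    dq_threshold: float = 0.2  # fraction of dish diameter per tick
    alpha: float = 0.5
    beta: float = 0.3


# ---------------------------------------------------------------------------
# stage 1: image processing
# ---------------------------------------------------------------------------


def init_background(frames: Sequence[np.ndarray], update_weight: float = 0.1) -> BackgroundModel:
    """Build the background as the per-pixel median of empty-dish frames.

    The median rejects transient bright specks (bubbles, reflections)
    present in a minority of the capture frames.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame to build a background")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all background frames must share one shape")
    bg = np.median(np.stack([np.asarray(f, dtype=np.float64) for f in frames]), axis=0)
    return BackgroundModel(background=bg, per_quadrant_age=np.zeros(4, dtype=np.int64),
                           update_weight=update_weight)


def heal_background(
    model: BackgroundModel,
    frame: np.ndarray,
    occupied_quadrants: Set[Quadrant],
    g: ArenaGeometry,
) -> BackgroundModel:
    """Refresh the background in every quadrant the animal is *not* in.

    Unoccupied quadrant regions blend toward the current frame with
    weight ``update_weight`` per tick, so the model follows slow drift
    (meniscus motion under microevaporation) without ever absorbing the
    animal itself.  Occupied quadrants are untouched and their age grows.
    """
    if frame.shape != model.background.shape:
        raise ValueError("frame shape does not match background model")
    labels = quadrant_label_image(g)
    bg = model.background.copy()
    ages = model.per_quadrant_age.copy()
    w = model.update_weight
    occupied = {q.value for q in occupied_quadrants}
    frame = np.asarray(frame, dtype=np.float64)
    for qi in range(4):
        region = labels == qi
        if qi in occupied:
            ages[qi] += 1
        else:
            bg[region] = (1.0 - w) * bg[region] + w * frame[region]
            ages[qi] = 0
    return BackgroundModel(background=bg, per_quadrant_age=ages, update_weight=w)


def subtract_and_stretch(
    frame: np.ndarray,
    model: BackgroundModel,
    expected_area_px: int,
    headroom: float = 2.0,
) -> np.ndarray:
    """Background-subtract and contrast-stretch a frame.

    The absolute difference image is linearly stretched so that the
    brightest ``headroom * expected_area_px`` pixels reach full scale:
    the value at the ``100 * (1 - headroom*A/N)``-th percentile maps to
    the dtype maximum and everything above clamps.  The stretch is
    scale-invariant, so downstream thresholding does not depend on the
    raw animal/background contrast.
    """
    if frame.shape != model.background.shape:
        raise ValueError("frame shape does not match background model")
    total = frame.size
    if expected_area_px < 1 or expected_area_px >= total:
        raise ValueError("expected_area_px must be in [1, total_pixels)")
    full_scale = 255.0 if frame.dtype != np.uint16 else 65535.0
    d = np.abs(np.asarray(frame, dtype=np.float64) - model.background)
    q = 100.0 * (1.0 - headroom * expected_area_px / total)
    pivot = float(np.percentile(d, q))
    if pivot <= 0.0:
        pivot = float(d.max())
        if pivot <= 0.0:
            return np.zeros_like(frame)
    out = np.clip(d / pivot, 0.0, 1.0) * full_scale
    return out.astype(frame.dtype)


def binarize(
    enhanced: np.ndarray,
    noise_k: float,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Threshold the enhanced image at ``mean + noise_k * std``.

    Statistics are taken over ``mask`` (normally the dish interior) so
    that dark corners outside the dish do not bias the noise estimate.
    A constant image yields an all-zero result rather than an error.
    """
    if noise_k <= 0:
        raise ValueError("noise_k must be positive")
    data = enhanced[mask] if mask is not None else enhanced
    t = float(np.mean(data)) + noise_k * float(np.std(data))
    binary = enhanced > t
    if mask is not None:
        binary = binary & mask
    return binary


def select_blobs(binary: np.ndarray, min_area_px: int) -> list:
    """8-connected component labelling with a minimum-area filter.

    Returns blobs sorted by area, largest first; the largest surviving
    blob is taken to be the animal.  Tiny components are noise artifacts
    and are dropped.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    labels = measure.label(binary, connectivity=2)
    blobs = []
    for rp in measure.regionprops(labels):
        if rp.area < min_area_px:
            continue
        cy, cx = rp.centroid
        blobs.append(
            Blob(
                centroid_px=(float(cx), float(cy)),
                area_px=int(rp.area),
                bbox=tuple(int(v) for v in rp.bbox),
                perimeter_px=float(rp.perimeter),
            )
        )
    blobs.sort(key=lambda b: b.area_px, reverse=True)
    return blobs


# ---------------------------------------------------------------------------
# stage 2: frame quality control
# ---------------------------------------------------------------------------


def qc_frame(
    candidate: Optional[Blob],
    prev: TrackState,
    dq_threshold: float,
    area_bounds: Tuple[int, int],
    g: ArenaGeometry,
    dt_ticks: int = 1,
) -> QCFlag:
    """Accept or reject a candidate detection.

    The jump test rejects displacements larger than ``dq_threshold``
    dish diameters per tick — implausible motion that indicates a
    tracking failure (a bubble, a reflection) rather than behaviour.
    While a frame is not accepted, the controller suppresses punishment
    so that artifacts cannot cause false training.
    """
    if not (0.0 <= dq_threshold <= 1.0):
        raise ValueError("dq_threshold must lie in [0, 1]")
    if candidate is None:
        return QCFlag.NO_BLOB
    if not (area_bounds[0] <= candidate.area_px <= area_bounds[1]):
        return QCFlag.REJECTED_AREA
    if prev.last_raw is not None:
        raw = px_to_mm(candidate.centroid_px, g)
        disp = math.hypot(raw[0] - prev.last_raw[0], raw[1] - prev.last_raw[1])
        if disp > dq_threshold * g.dish_diameter_mm * max(dt_ticks, 1):
            return QCFlag.REJECTED_JUMP
    return QCFlag.ACCEPTED


# ---------------------------------------------------------------------------
# stage 3: smoothing
# ---------------------------------------------------------------------------


def smooth(prev: TrackState, raw: Tuple[float, float]) -> TrackState:
    """One step of Holt double-exponential smoothing.

    level' = alpha*raw + (1-alpha)*(level + trend)
    trend' = beta*(level' - level) + (1-beta)*trend

    The first accepted observation initializes the state at the raw
    position with zero trend.  Both components are smoothed jointly
    (identical to componentwise for these linear recurrences).
    """
    if not prev.initialized:
        return replace(prev, level=raw, trend=(0.0, 0.0), last_raw=raw, qc_flag=QCFlag.ACCEPTED)
    a, b = prev.alpha, prev.beta
    lx, ly = prev.level
    tx, ty = prev.trend
    nlx = a * raw[0] + (1.0 - a) * (lx + tx)
    nly = a * raw[1] + (1.0 - a) * (ly + ty)
    ntx = b * (nlx - lx) + (1.0 - b) * tx
    nty = b * (nly - ly) + (1.0 - b) * ty
    return replace(prev, level=(nlx, nly), trend=(ntx, nty), last_raw=raw,
                   qc_flag=QCFlag.ACCEPTED)


def _coast(prev: TrackState, flag: QCFlag) -> TrackState:
    return replace(prev, qc_flag=flag)


def _blob_quadrants(blob: Blob, g: ArenaGeometry) -> Set[Quadrant]:
    """Quadrants overlapped by a blob's bounding box (plus a 2 px pad).

    Healing must skip *every* quadrant the animal touches, not just the
    centroid's: a body straddling a vane would otherwise be blended
    into the neighbouring quadrant's background and bias the centroid.
    """
    r0, c0, r1, c1 = blob.bbox
    pad = 2
    occupied: Set[Quadrant] = set()
    for py in (r0 - pad, r1 + pad):
        for px in (c0 - pad, c1 + pad):
            p = px_to_mm((px, py), g)
            r = math.hypot(p[0], p[1])
            if r > g.dish_radius_mm:
                p = (p[0] * g.dish_radius_mm / r, p[1] * g.dish_radius_mm / r)
            occupied.add(quadrant_of(p, g))
    return occupied


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def track_frame(
    frame: np.ndarray,
    model: BackgroundModel,
    prev: TrackState,
    params: TrackingParams,
    g: ArenaGeometry,
    heal: bool = True,
) -> Tuple[TrackState, BackgroundModel, Optional[Blob]]:
    """Process one frame end to end.

    Runs subtraction/stretch, thresholding, blob selection, QC and
    smoothing, then heals the background in every quadrant that does
    not contain the accepted animal.  On a rejected frame the state
    coasts and the background is left alone (the animal's location is
    unknown, so no quadrant can safely be declared empty).
    """
    enhanced = subtract_and_stretch(frame, model, params.expected_area_px,
                                    params.stretch_headroom)
    binary = binarize(enhanced, params.noise_k, mask=dish_mask(g))
    blobs = select_blobs(binary, params.min_area_px)
    candidate = blobs[0] if blobs else None
    flag = qc_frame(candidate, prev, params.dq_threshold, params.area_bounds, g)
    if flag is QCFlag.ACCEPTED:
        raw = px_to_mm(candidate.centroid_px, g)
        state = smooth(prev, raw)
        if heal:
            model = heal_background(model, frame, _blob_quadrants(candidate, g), g)
    else:
        state = _coast(prev, flag)
    return state, model, candidate
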