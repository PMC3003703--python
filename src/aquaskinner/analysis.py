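"""Post-trial analytics: log parsing, time-segment binning, occupancy
("curiosity") maps, region preference and exploration statistics.

All behavioural statistics are computed over *accepted* ticks only:
quality-rejected rows are tracking artifacts, not behaviour, so they
are retained in the record but excluded from every denominator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .arena import ArenaGeometry, mm_to_px
from .controller import LOG_COLUMNS

__all__ = [
    "read_log",
    "write_log",
    "time_segments",
    "OccupancyMap",
    "occupancy_map",
    "render_occupancy",
    "region_preference",
    "explored_fraction",
    "LogFormatError",
]

#: default band (mm from the wall) counted as "edge" time
DEFAULT_EDGE_BAND_MM = 5.0
#: default exploration grid cell, mm (~two body widths of a small planarian)
DEFAULT_EXPLORE_CELL_MM = 2.0


class LogFormatError(ValueError):
    """The trial log violates the schema."""


def write_log(df: pd.DataFrame, path) -> None:
    """Write a trial record as the canonical CSV log."""
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise LogFormatError(f"record is missing columns: {missing}")
    out = df[list(LOG_COLUMNS)].copy()
    out.to_csv(path, index=False, float_format="%.3f")


def read_log(path) -> pd.DataFrame:
    """Read and validate a trial log.

    Checks the header against the schema, reports malformed rows by
    line number, and requires time to be strictly monotone within each
    channel.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != list(LOG_COLUMNS):
        for i, (got, want) in enumerate(zip(df.columns, LOG_COLUMNS)):
            if got != want:
                raise LogFormatError(
                    f"schema mismatch at column {i}: expected {want!r}, found {got!r}"
                )
        raise LogFormatError(
            f"schema mismatch: expected {len(LOG_COLUMNS)} columns, found {len(df.columns)}"
        )
    numeric = {
        "time_s": float, "channel": int, "blob_area_px": int, "shock_on": int,
        "shock_mA": float,
        **{f"red_q{i}": int for i in range(1, 5)},
        **{f"blue_q{i}": int for i in range(1, 5)},
    }
    out = df.copy()
    for col, typ in numeric.items():
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col] != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based plus header row
            raise LogFormatError(f"malformed value {df[col][bad.idxmax()]!r} in column "
                                 f"{col!r} at line {line}")
        out[col] = converted.astype(typ) if not converted.isna().any() else converted
    for col in ("x_mm", "y_mm", "speed_mm_s"):
        converted = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        bad = converted.isna() & (df[col] != "")
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise LogFormatError(f"malformed value in column {col!r} at line {line}")
        out[col] = converted
    for ch, grp in out.groupby("channel"):
        t = grp["time_s"].to_numpy()
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise LogFormatError(f"non-monotone time in channel {ch}")
    return out


def _accepted(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["qc_flag"] == "accepted"]


def _channel(df: pd.DataFrame, channel: Optional[int]) -> pd.DataFrame:
    if channel is None:
        chans = df["channel"].unique()
        if len(chans) > 1:
            raise ValueError("record has multiple channels; pass channel=")
        return df
    return df[df["channel"] == channel]


def time_segments(
    df: pd.DataFrame,
    bin_s: float,
    channel: Optional[int] = None,
    g: ArenaGeometry = ArenaGeometry(),
    edge_band_mm: float = DEFAULT_EDGE_BAND_MM,
    explore_cell_mm: float = DEFAULT_EXPLORE_CELL_MM,
) -> pd.DataFrame:
    """Bin one channel's record into fixed time segments.

    Bins are half-open ``[k*bin_s, (k+1)*bin_s)``; a trailing partial
    bin is emitted with ``partial=True``.  Per bin: fraction of
    accepted time in each quadrant, mean speed, fraction of ticks
    punished, fraction of time within ``edge_band_mm`` of the wall, and
    the cumulative explored-area fraction at the bin's end.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    rec = _channel(df, channel)
    if rec.empty:
        return pd.DataFrame()
    t_last = float(rec["time_s"].max())
    ts = rec["time_s"].to_numpy()
    dt = float(np.median(np.diff(ts))) if len(ts) > 1 else 0.0
    t_end = t_last + dt  # record spans [0, last tick + one period)
    n_bins = int(t_last // bin_s) + 1
    acc_all = _accepted(rec)
    visited: set = set()
    rows = []
    for k in range(n_bins):
        lo, hi = k * bin_s, (k + 1) * bin_s
        seg = rec[(rec["time_s"] >= lo) & (rec["time_s"] < hi)]
        acc = _accepted(seg)
        n = len(acc)
        qf = [float((acc["quadrant"] == f"Q{i}").sum()) / n if n else 0.0 for i in range(1, 5)]
        if n:
            r = np.hypot(acc["x_mm"], acc["y_mm"])
            edge_frac = float((g.dish_radius_mm - r < edge_band_mm).mean())
            for x, y in zip(acc["x_mm"], acc["y_mm"]):
                visited.add((int(math.floor(x / explore_cell_mm)),
                             int(math.floor(y / explore_cell_mm))))
        else:
            edge_frac = 0.0
        rows.append(
            {
                "bin_start_s": lo,
                "bin_end_s": hi,
                "n_ticks": len(seg),
                "n_accepted": n,
                **{f"quadrant_fraction_q{i}": qf[i - 1] for i in range(1, 5)},
                "mean_speed_mm_s": float(acc["speed_mm_s"].mean()) if n else math.nan,
                "punished_fraction": float(acc["shock_on"].mean()) if n else 0.0,
                "edge_fraction": edge_frac,
                "explored_fraction": len(visited) / _n_dish_cells(g, explore_cell_mm),
                "partial": hi > t_end + 1e-6,
            }
        )
    return pd.DataFrame(rows)


def _n_dish_cells(g: ArenaGeometry, cell_mm: float) -> int:
    """Number of grid cells whose centre lies inside the dish."""
    n = int(math.ceil(g.dish_radius_mm / cell_mm)) + 1
    count = 0
    for i in range(-n, n):
        for j in range(-n, n):
            cx = (i + 0.5) * cell_mm
            cy = (j + 0.5) * cell_mm
            if cx * cx + cy * cy < g.dish_radius_mm**2:
                count += 1
    return count


@dataclass
class OccupancyMap:
    """Grid of visit counts over the dish bounding box.

    Each accepted tick stamps a disc of radius ``stamp_radius_px``
    around the animal's position, so total mass equals
    ``n_ticks * stamp_cells`` minus whatever clips off the grid edge
    (reported in ``clipped_mass``).
    """

    counts: np.ndarray
    stamp_radius_px: int
    n_ticks: int
    stamp_cells: int
    clipped_mass: int

    def total_mass(self) -> int:
        return int(self.counts.sum())


def occupancy_map(
    df: pd.DataFrame,
    stamp_radius_px: int = 3,
    grid_shape: Optional[Tuple[int, int]] = None,
    channel: Optional[int] = None,
    g: ArenaGeometry = ArenaGeometry(),
) -> OccupancyMap:
    """Accumulate the classic pseudocolour occupancy ("curiosity") map.

    For every accepted tick all grid cells within ``stamp_radius_px``
    of the position are incremented; where stamps overlap the count —
    and hence the rendered colour — rises.
    """
    if stamp_radius_px < 0:
        raise ValueError("stamp_radius_px must be >= 0")
    rec = _accepted(_channel(df, channel))
    shape = grid_shape or (g.image_height_px, g.image_width_px)
    counts = np.zeros(shape, dtype=np.int64)

    r = stamp_radius_px
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    stamp = (xx * xx + yy * yy) <= r * r
    stamp_cells = int(stamp.sum())
    clipped = 0
    for x, y in zip(rec["x_mm"], rec["y_mm"]):
        px, py = mm_to_px((x, y), g)
        ci, cj = int(round(py)), int(round(px))
        i0, i1 = ci - r, ci + r + 1
        j0, j1 = cj - r, cj + r + 1
        si0, sj0 = max(0, -i0), max(0, -j0)
        i0c, j0c = max(i0, 0), max(j0, 0)
        i1c, j1c = min(i1, shape[0]), min(j1, shape[1])
        if i1c <= i0c or j1c <= j0c:
            clipped += stamp_cells
            continue
        sub = stamp[si0 : si0 + (i1c - i0c), sj0 : sj0 + (j1c - j0c)]
        counts[i0c:i1c, j0c:j1c] += sub
        clipped += stamp_cells - int(sub.sum())
    return OccupancyMap(counts=counts, stamp_radius_px=r, n_ticks=len(rec),
                        stamp_cells=stamp_cells, clipped_mass=clipped)


def render_occupancy(
    omap: OccupancyMap,
    png_path=None,
    quantiles: Tuple[float, float, float] = (0.5, 0.75, 0.9),
) -> np.ndarray:
    """Map counts to the blue-green-yellow-red ramp.

    Breakpoints sit at count quantiles (over visited cells), so the
    rendering is rank-preserving: a higher count never maps to a cooler
    colour.  Returns the RGB image; optionally writes a PNG.
    """
    from matplotlib import colors

    counts = omap.counts.astype(float)
    visited = counts[counts > 0]
    rgb = np.zeros(counts.shape + (3,))
    if visited.size:
        qs = np.quantile(visited, quantiles)
        ramp = colors.LinearSegmentedColormap.from_list(
            "curiosity", ["#00169c", "#00a03c", "#e0d000", "#d01000"]
        )
        # piecewise rank mapping through the quantile breakpoints
        levels = np.zeros_like(counts)
        edges = [0.0, *qs, max(float(visited.max()), qs[-1] + 1.0)]
        for i in range(len(edges) - 1):
            lo, hi = edges[i], edges[i + 1]
            m = (counts > lo) & (counts <= hi)
            span = hi - lo if hi > lo else 1.0
            levels[m] = (i + (counts[m] - lo) / span) / (len(edges) - 1)
        rgb = ramp(levels)[..., :3]
        rgb[counts == 0] = 1.0  # unvisited stays white
    if png_path is not None:
        import imageio.v3 as iio

        iio.imwrite(png_path, (rgb * 255).astype(np.uint8))
    return rgb


def default_region_label(red: int, blue: int) -> str:
    """Colour label of a quadrant from its logged levels: the dominant
    (brighter) colour names the region; ties count as red background."""
    return "blue" if blue > red else "red"


def region_preference(
    df: pd.DataFrame,
    channel: Optional[int] = None,
    label_fn: Callable[[int, int], str] = default_region_label,
) -> Dict[str, float]:
    """Fraction of accepted time under each lighting label.

    A tick's label comes from the *logged* light levels of the quadrant
    the animal occupied, so rotations are tracked exactly as the animal
    experienced them rather than from the static configuration.
    """
    rec = _accepted(_channel(df, channel))
    if rec.empty:
        return {}
    quads = rec["quadrant"].str[1].astype(int)  # 1..4
    labels = []
    for (_, row), q in zip(rec.iterrows(), quads):
        labels.append(label_fn(int(row[f"red_q{q}"]), int(row[f"blue_q{q}"])))
    ser = pd.Series(labels)
    return ser.value_counts(normalize=True).to_dict()


def explored_fraction(
    df: pd.DataFrame,
    cell_mm: float = DEFAULT_EXPLORE_CELL_MM,
    channel: Optional[int] = None,
    g: ArenaGeometry = ArenaGeometry(),
) -> float:
    """Cumulative fraction of the dish visited, on a ``cell_mm`` grid."""
    if cell_mm <= 0:
        raise ValueError("cell_mm must be positive")
    rec = _accepted(_channel(df, channel))
    visited = {
        (int(math.floor(x / cell_mm)), int(math.floor(y / cell_mm)))
        for x, y in zip(rec["x_mm"], rec["y_mm"])
    }
    return len(visited) / _n_dish_cells(g, cell_mm)


def trial_report(
    df: pd.DataFrame,
    bin_s: float = 300.0,
    g: ArenaGeometry = ArenaGeometry(),
) -> Dict:
    """JSON-ready per-channel summary of a whole trial."""
    report = {}
    for ch in sorted(df["channel"].unique()):
        segs = time_segments(df, bin_s, channel=int(ch), g=g)
        report[int(ch)] = {
            "n_ticks": int((df["channel"] == ch).sum()),
            "accepted_fraction": float((_channel(df, int(ch))["qc_flag"] == "accepted").mean()),
            "region_preference": region_preference(df, channel=int(ch)),
            "explored_fraction": explored_fraction(df, channel=int(ch), g=g),
            "punished_fraction": float(_accepted(_channel(df, int(ch)))["shock_on"].mean())
            if len(_accepted(_channel(df, int(ch))))
            else 0.0,
            "segments": segs.to_dict(orient="records"),
        }
    return report
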