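"""Current-density model of the in-dish shock field.

The dish is a thin conductive layer (the electrodes span the full water
depth, so the field is depth-independent and the problem is
two-dimensional).  With uniform conductivity the potential satisfies
Laplace's equation; driven electrode arcs on the wall are Dirichlet
boundaries at +/-V0 and the rest of the wall (including inactive
electrodes) is insulating.  Current density is J = -sigma * grad V; the
conductivity is a global scale factor and is left absorbed in the
units, since every homogeneity statistic reported here is
scale-invariant.

The solver is a finite-difference scheme on a regular grid with an
embedded-boundary disk mask: interior cells carry the standard 5-point
Laplacian, cells missing a neighbour across the wall get the zero-flux
(mirror) closure, and boundary cells under an active electrode arc are
held at the excitation potential.  The sparse system is solved
directly; the residual is verified against ``tol``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .arena import ArenaGeometry

__all__ = [
    "ExcitationSpec",
    "FieldSolution",
    "solve_phase",
    "phase_excitations",
    "rotating_average",
    "homogeneity_fraction",
    "coefficient_of_variation",
    "compare_configs",
]


@dataclass(frozen=True)
class ExcitationSpec:
    """Role of each electrode during one excitation phase.

    ``roles[i]`` is +1 (source, +V0), -1 (sink, -V0) or 0 (inactive,
    treated as insulating wall).
    """

    roles: Tuple[int, ...]
    v0: float = 20.0

    def __post_init__(self) -> None:
        if not any(r > 0 for r in self.roles) or not any(r < 0 for r in self.roles):
            raise ValueError("excitation needs at least one source and one sink")
        if any(r not in (-1, 0, 1) for r in self.roles):
            raise ValueError("roles must be -1, 0 or +1")


@dataclass
class FieldSolution:
    """Discrete potential and current density over the dish."""

    potential: np.ndarray  # V, NaN outside the dish
    jx: np.ndarray
    jy: np.ndarray
    jmag: np.ndarray  # |J|, NaN outside the dish
    in_dish: np.ndarray  # bool mask of dish cells
    h_mm: float
    electrode_cells: np.ndarray  # bool mask of Dirichlet cells


def _grid(g: ArenaGeometry, h_mm: float):
    R = g.dish_radius_mm
    n = int(math.ceil(2.0 * R / h_mm)) + 1
    xs = (np.arange(n) - (n - 1) / 2.0) * h_mm
    X, Y = np.meshgrid(xs, xs, indexing="xy")
    return n, X, Y


def solve_phase(
    g: ArenaGeometry,
    exc: ExcitationSpec,
    h_mm: float = 0.25,
    tol: float = 1e-8,
) -> FieldSolution:
    """Solve one excitation phase for potential and current density.

    Parameters
    ----------
    g:
        Arena geometry; electrode arcs are centred on
        ``electrode_angles_deg`` with width ``electrode_arc_deg``,
        flush with the dish wall.
    h_mm:
        Grid spacing; at least 50 cells must span the dish diameter.
    tol:
        Maximum allowed relative residual of the discrete system.
    """
    if len(exc.roles) != g.n_electrodes:
        raise ValueError("excitation roles must match electrode count")
    R = g.dish_radius_mm
    if 2.0 * R / h_mm < 50:
        raise ValueError("grid too coarse: need >= 50 cells across the dish")
    n, X, Y = _grid(g, h_mm)
    r = np.hypot(X, Y)
    in_dish = r < R
    theta = np.degrees(np.arctan2(Y, X)) % 360.0

    # wall cells = dish cells with at least one 4-neighbour outside
    outside_nb = np.zeros(in_dish.shape, dtype=np.int8)
    for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
        rolled = np.roll(in_dish, sh, axis=ax)
        # roll wraps; wrapped-in cells are outside the dish anyway at the rim
        outside_nb += ~rolled
    wall = in_dish & (outside_nb > 0)

    dirichlet = np.zeros(in_dish.shape)
    is_dirichlet = np.zeros(in_dish.shape, dtype=bool)
    for i, ang in enumerate(g.electrode_angles_deg):
        if exc.roles[i] == 0:
            continue
        dth = np.abs((theta - ang + 180.0) % 360.0 - 180.0)
        cells = wall & (dth <= g.electrode_arc_deg / 2.0)
        is_dirichlet |= cells
        dirichlet[cells] = exc.roles[i] * exc.v0

    unknown = in_dish & ~is_dirichlet
    N = int(unknown.sum())
    index = -np.ones(in_dish.shape, dtype=np.int64)
    index[unknown] = np.arange(N)
    ii, jj = np.nonzero(unknown)

    rows: List[np.ndarray] = []
    cols: List[np.ndarray] = []
    vals: List[np.ndarray] = []
    diag = np.zeros(N)
    b = np.zeros(N)
    for di, dj in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        ni, nj = ii + di, jj + dj
        inside = (ni >= 0) & (ni < n) & (nj >= 0) & (nj < n)
        nin = np.zeros(len(ii), dtype=bool)
        nin[inside] = in_dish[ni[inside], nj[inside]]
        # neighbour outside the dish -> zero-flux closure: term dropped
        diag[index[ii[nin], jj[nin]]] += 1.0
        ncl = (np.clip(ni, 0, n - 1), np.clip(nj, 0, n - 1))
        ndir = nin & is_dirichlet[ncl]
        nunk = nin & ~is_dirichlet[ncl]
        rows.append(index[ii[nunk], jj[nunk]])
        cols.append(index[ni[nunk], nj[nunk]])
        vals.append(-np.ones(int(nunk.sum())))
        np.add.at(b, index[ii[ndir], jj[ndir]], dirichlet[ni[ndir], nj[ndir]])
    rows.append(np.arange(N))
    cols.append(np.arange(N))
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(N, N)
    )
    x = spla.spsolve(A, b)
    resid = np.linalg.norm(A @ x - b)
    scale = max(np.linalg.norm(b), 1.0)
    if not np.isfinite(x).all() or resid / scale > max(tol, 1e-10):
        raise RuntimeError(f"field solve did not converge: relative residual {resid / scale:.2e}")

    V = np.full(in_dish.shape, np.nan)
    V[unknown] = x
    V[is_dirichlet] = dirichlet[is_dirichlet]

    jx, jy, jmag = _current_density(V, in_dish, h_mm)
    return FieldSolution(potential=V, jx=jx, jy=jy, jmag=jmag, in_dish=in_dish,
                         h_mm=h_mm, electrode_cells=is_dirichlet)


def _current_density(V: np.ndarray, in_dish: np.ndarray, h: float):
    """J = -grad V by central differences; one-sided at the dish rim.

    Every in-dish cell receives a value so that area statistics cover
    the whole dish, matching the "fraction of dish area" convention.
    """
    n = V.shape[0]
    ii, jj = np.nonzero(in_dish)

    def neighbour(di: int, dj: int) -> np.ndarray:
        ni, nj = ii + di, jj + dj
        out = np.full(len(ii), np.nan)
        ok = (ni >= 0) & (ni < n) & (nj >= 0) & (nj < n)
        out[ok] = V[ni[ok], nj[ok]]
        return out

    v0 = V[ii, jj]
    grads = []
    for da, db in (((0, 1), (0, -1)), ((1, 0), (-1, 0))):
        vp, vm = neighbour(*da), neighbour(*db)
        central = (vp - vm) / (2.0 * h)
        fwd = (vp - v0) / h
        bwd = (v0 - vm) / h
        grad = np.where(
            np.isfinite(vp) & np.isfinite(vm),
            central,
            np.where(np.isfinite(vp), fwd, np.where(np.isfinite(vm), bwd, 0.0)),
        )
        grads.append(grad)
    gx, gy = grads
    jx = np.full(V.shape, np.nan)
    jy = np.full(V.shape, np.nan)
    jmag = np.full(V.shape, np.nan)
    jx[ii, jj] = -gx
    jy[ii, jj] = -gy
    jmag[ii, jj] = np.hypot(gx, gy)
    return jx, jy, jmag


def phase_excitations(schedule, v0: float = 20.0) -> List[ExcitationSpec]:
    """Excitation specs for every phase of a rotating schedule."""
    specs = []
    for sources, sinks in schedule.phase_roles():
        roles = [0] * schedule.n_electrodes
        for s in sources:
            roles[s] = 1
        for s in sinks:
            roles[s] = -1
        specs.append(ExcitationSpec(roles=tuple(roles), v0=v0))
    return specs


def rotating_average(
    g: ArenaGeometry,
    schedule,
    v0: float = 20.0,
    h_mm: float = 0.25,
    tol: float = 1e-8,
) -> Tuple[np.ndarray, np.ndarray]:
    """Time-averaged |J| over the rotating excitation schedule.

    All phases dwell equally (8 ms each), so the average is unweighted.
    Returns ``(jmag_avg, in_dish_mask)``.
    """
    total: Optional[np.ndarray] = None
    mask = None
    for exc in phase_excitations(schedule, v0):
        sol = solve_phase(g, exc, h_mm=h_mm, tol=tol)
        if total is None:
            total = np.zeros_like(sol.jmag)
            mask = sol.in_dish
        total[mask] += sol.jmag[mask]
    total[mask] /= schedule.n_phases
    total[~mask] = np.nan
    return total, mask


def homogeneity_fraction(jmag: np.ndarray, band: float, mask: np.ndarray) -> float:
    """Fraction of dish area with |J| within ``band`` of its mean.

    ``band=0.3`` asks for the area where
    ``0.7*mean <= |J| <= 1.3*mean``, the statistic quoted for the
    rotating six-electrode excitation.
    """
    if not (0.0 < band < 1.0):
        raise ValueError("band must lie in (0, 1)")
    vals = jmag[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty mask")
    m = float(vals.mean())
    ok = (vals >= (1.0 - band) * m) & (vals <= (1.0 + band) * m)
    return float(ok.mean())


def coefficient_of_variation(jmag: np.ndarray, mask: np.ndarray) -> float:
    vals = jmag[mask]
    vals = vals[np.isfinite(vals)]
    return float(vals.std() / vals.mean())


def compare_configs(
    g: ArenaGeometry,
    h_mm: float = 0.25,
    band: float = 0.3,
    v0: float = 20.0,
) -> Dict[str, float]:
    """Homogeneity of the three classic electrode configurations.

    * ``dipole`` — one antipodal source/sink pair, the conventional
      2-electrode design (anisotropic, hot spots at the poles);
    * ``static_quadrupole`` — one frozen phase of the 6-electrode
      schedule (2 adjacent sources, 2 opposite sinks);
    * ``rotating_hexapole`` — the 6-phase rotating excitation averaged
      over a full rotation.

    Returns the band-homogeneity fraction for each.
    """
    from .controller import build_phase_schedule

    schedule = build_phase_schedule(n_electrodes=g.n_electrodes)
    half = g.n_electrodes // 2
    dip_roles = [0] * g.n_electrodes
    dip_roles[0], dip_roles[half] = 1, -1
    dip = solve_phase(g, ExcitationSpec(roles=tuple(dip_roles), v0=v0), h_mm=h_mm)
    static = solve_phase(g, phase_excitations(schedule, v0)[0], h_mm=h_mm)
    rot, mask = rotating_average(g, schedule, v0=v0, h_mm=h_mm)
    return {
        "dipole": homogeneity_fraction(dip.jmag, band, dip.in_dish),
        "static_quadrupole": homogeneity_fraction(static.jmag, band, static.in_dish),
        "rotating_hexapole": homogeneity_fraction(rot, band, mask),
    }


def net_boundary_current(sol: FieldSolution) -> float:
    """Net current into the dish across electrode cells, relative to the
    total driven current (should vanish by conservation)."""
    V, h, mask = sol.potential, sol.h_mm, sol.in_dish
    n = V.shape[0]
    total = 0.0
    gross = 0.0
    ii, jj = np.nonzero(sol.electrode_cells)
    for i, j in zip(ii, jj):
        for di, dj in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            ni, nj = i + di, j + dj
            if 0 <= ni < n and 0 <= nj < n and mask[ni, nj] and not sol.electrode_cells[ni, nj]:
                flux = (V[i, j] - V[ni, nj]) / h  # current leaving the electrode cell
                total += flux
                gross += abs(flux)
    return total / gross if gross > 0 else 0.0
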