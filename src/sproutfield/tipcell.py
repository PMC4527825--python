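"""Tip-cell traction field and its relocation schedule.

The tip cell is represented purely by the contractile traction it exerts on
the tissue, encoded as a compactly supported scalar potential chi_t with
f_t = -grad(chi_t).  Every ``t_cell`` (about 5 minutes) the sprout front is
re-detected on the phi = 0 level set and the potential is re-centred there,
oriented along the local VEGF gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

from .grid import GridSpec, ScalarField, gradient

__all__ = [
    "TipCell",
    "TipSchedule",
    "SproutLostError",
    "build_chi",
    "interface_points",
    "locate_tip",
    "maybe_reposition",
]


class SproutLostError(RuntimeError):
    """No phi = 0 interface found within the tip's search radius."""


@dataclass(frozen=True)
class TipCell:
    """Centre, orientation and strength of the traction potential.

    ``amplitude`` is the peak traction in kPa (the study range is 0-6 kPa);
    ``radius`` defaults to 5 um, the approximate radius of an endothelial
    cell.  ``anisotropy`` selects the angular profile: ``"none"`` for a
    radially symmetric bump, ``"forward"`` for (1 + cos(theta))/2 relative
    to ``direction``.
    """

    center: Tuple[float, float]
    direction: Tuple[float, float] = (1.0, 0.0)
    amplitude: float = 3.0
    radius: float = 5.0
    anisotropy: str = "none"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("traction amplitude must be non-negative")
        if self.radius <= 0:
            raise ValueError("tip radius must be positive")
        if self.anisotropy not in ("none", "forward"):
            raise ValueError(f"unknown anisotropy {self.anisotropy!r}")
        n = float(np.hypot(*self.direction))
        if not np.isfinite(n) or n == 0:
            raise ValueError("tip direction must be a nonzero vector")
        object.__setattr__(
            self, "direction", (self.direction[0] / n, self.direction[1] / n)
        )


@dataclass(frozen=True)
class TipSchedule:
    """Relocation clock: the force field is re-centred every t_cell minutes."""

    t_cell_min: float = 5.0
    last_update_hr: float = 0.0

    def __post_init__(self) -> None:
        if self.t_cell_min <= 0:
            raise ValueError("t_cell must be positive")

    @property
    def t_cell_hr(self) -> float:
        return self.t_cell_min / 60.0

    def due(self, t_hr: float) -> bool:
        return t_hr - self.last_update_hr >= self.t_cell_hr - 1e-12


def build_chi(tip: TipCell, grid: GridSpec) -> ScalarField:
    """Traction potential chi_t on the grid.

    chi_t(r) = amplitude * cos^2(pi*rho/2) * A(theta) for rho = |r - c|/radius
    < 1 and exactly zero outside the disc; the radial bump is C1 at the rim.
    """
    x0, y0 = grid.origin
    lx, ly = grid.extent
    cx, cy = tip.center
    if not (x0 <= cx <= x0 + lx and y0 <= cy <= y0 + ly):
        raise ValueError(f"tip centre {tip.center} lies outside the grid")
    X, Y = grid.coords()
    dx, dy = X - cx, Y - cy
    rho = np.hypot(dx, dy) / tip.radius
    inside = rho < 1.0
    chi = np.zeros(grid.shape)
    chi[inside] = tip.amplitude * np.cos(0.5 * np.pi * rho[inside]) ** 2
    if tip.anisotropy == "forward":
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.hypot(dx, dy)
            cos_t = np.where(
                r > 0, (dx * tip.direction[0] + dy * tip.direction[1]) / np.maximum(r, 1e-30), 1.0
            )
        chi[inside] *= 0.5 * (1.0 + cos_t[inside])
    return ScalarField(grid, chi)


def interface_points(phi: ScalarField) -> np.ndarray:
    """All phi = 0 crossings, linearly interpolated on grid edges.

    Returns an (n, 2) array of physical (x, y) positions; empty if phi does
    not change sign anywhere.
    """
    v = phi.values
    h = phi.grid.h
    x0, y0 = phi.grid.origin
    pts = []

    # edges along x: nodes (i, j) and (i+1, j)
    a, b = v[:-1, :], v[1:, :]
    mask = (a * b < 0) | ((a == 0) & (b != 0))
    ii, jj = np.nonzero(mask)
    if ii.size:
        frac = a[ii, jj] / (a[ii, jj] - b[ii, jj])
        pts.append(np.column_stack([x0 + (ii + frac) * h, y0 + jj * h]))

    # edges along y
    a, b = v[:, :-1], v[:, 1:]
    mask = (a * b < 0) | ((a == 0) & (b != 0))
    ii, jj = np.nonzero(mask)
    if ii.size:
        frac = a[ii, jj] / (a[ii, jj] - b[ii, jj])
        pts.append(np.column_stack([x0 + ii * h, y0 + (jj + frac) * h]))

    if not pts:
        return np.empty((0, 2))
    return np.vstack(pts)


def locate_tip(
    phi: ScalarField,
    V: ScalarField,
    previous: TipCell,
    search_radius: float = 15.0,
) -> Tuple[float, float]:
    """Sprout front: the interface point most advanced along the VEGF gradient.

    Candidates are phi = 0 crossings within ``search_radius`` of the previous
    centre; the winner maximizes the projection of its displacement from the
    previous centre onto the locally normalized grad(V).  Ties break toward
    smaller y, then smaller x.  Raises :class:`SproutLostError` when no
    candidate exists.
    """
    pts = interface_points(phi)
    if pts.shape[0] == 0:
        raise SproutLostError("no phi=0 interface anywhere in the domain")
    d = np.hypot(pts[:, 0] - previous.center[0], pts[:, 1] - previous.center[1])
    near = pts[d <= search_radius]
    if near.shape[0] == 0:
        raise SproutLostError(
            f"no interface within {search_radius} um of {previous.center}"
        )
    gv = gradient(V)
    h = phi.grid.h
    x0, y0 = phi.grid.origin
    i = np.clip(np.rint((near[:, 0] - x0) / h).astype(int), 0, phi.grid.nx - 1)
    j = np.clip(np.rint((near[:, 1] - y0) / h).astype(int), 0, phi.grid.ny - 1)
    gx, gy = gv.x[i, j], gv.y[i, j]
    norm = np.hypot(gx, gy)
    fallback = np.array(previous.direction)
    gx = np.where(norm > 1e-14, gx / np.maximum(norm, 1e-300), fallback[0])
    gy = np.where(norm > 1e-14, gy / np.maximum(norm, 1e-300), fallback[1])
    score = (near[:, 0] - previous.center[0]) * gx + (
        near[:, 1] - previous.center[1]
    ) * gy
    # lexicographic tie-break: highest score, then smallest y, then smallest x
    order = np.lexsort((near[:, 0], near[:, 1], -score))
    best = near[order[0]]
    return float(best[0]), float(best[1])


def _grad_at(V: ScalarField, point: Tuple[float, float]) -> Tuple[float, float]:
    gv = gradient(V)
    h = V.grid.h
    x0, y0 = V.grid.origin
    i = int(np.clip(round((point[0] - x0) / h), 0, V.grid.nx - 1))
    j = int(np.clip(round((point[1] - y0) / h), 0, V.grid.ny - 1))
    return float(gv.x[i, j]), float(gv.y[i, j])


def maybe_reposition(
    t_hr: float,
    tip: TipCell,
    schedule: TipSchedule,
    phi: ScalarField,
    V: ScalarField,
    search_radius: float = 15.0,
) -> Tuple[TipCell, TipSchedule, bool]:
    """Re-centre the traction field on the current front if t_cell has elapsed.

    Returns ``(tip, schedule, moved)``.  On relocation the new direction is
    the normalized VEGF gradient at the new centre (previous direction kept
    if the gradient vanishes there); amplitude and radius are unchanged.
    """
    if not schedule.due(t_hr):
        return tip, schedule, False
    center = locate_tip(phi, V, tip, search_radius)
    gx, gy = _grad_at(V, center)
    n = float(np.hypot(gx, gy))
    direction = (gx / n, gy / n) if n > 1e-14 else tip.direction
    new_tip = replace(tip, center=center, direction=direction)
    return new_tip, TipSchedule(schedule.t_cell_min, t_hr), True
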