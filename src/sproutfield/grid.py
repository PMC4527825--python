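"""Uniform 2-D grid, boundary policies and finite-difference stencils.

All physical fields in the model (order parameter phi, VEGF concentration V,
displacement potential w, traction potential chi_t, strain s, proliferation
source alpha_p) live on the same node-centered uniform grid.  Node ``(i, j)``
sits at ``(x0 + i*h, y0 + j*h)``; arrays are indexed ``values[i, j]`` with
axis 0 along x and axis 1 along y.

Lengths are micrometres, time is hours, stresses are kPa throughout the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple, Union

import numpy as np
from scipy import ndimage

__all__ = [
    "GridSpec",
    "ScalarField",
    "VectorField",
    "BoundaryPolicy",
    "NO_FLUX",
    "PERIODIC",
    "dirichlet",
    "laplacian",
    "second_derivative",
    "gradient",
    "divergence",
    "disc_mean",
    "disc_kernel",
]


# --------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the node-centered uniform grid.

    Parameters
    ----------
    nx, ny
        Node counts along x and y.  At least 8 each so that every stencil
        has a genuine interior.
    h
        Grid spacing in micrometres (square cells).
    origin
        Physical position of node (0, 0) in micrometres.
    """

    nx: int
    ny: int
    h: float = 1.0
    origin: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise ValueError(f"grid must be at least 8x8, got {self.nx}x{self.ny}")
        if self.h <= 0:
            raise ValueError(f"grid spacing must be positive, got {self.h}")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.nx, self.ny)

    @property
    def extent(self) -> Tuple[float, float]:
        """Physical size (Lx, Ly) of the domain in micrometres."""
        return ((self.nx - 1) * self.h, (self.ny - 1) * self.h)

    def coords(self) -> Tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays X, Y of node positions, shape (nx, ny)."""
        x = self.origin[0] + self.h * np.arange(self.nx)
        y = self.origin[1] + self.h * np.arange(self.ny)
        return np.meshgrid(x, y, indexing="ij")

    def cell_area(self) -> float:
        return self.h * self.h


@dataclass
class ScalarField:
    """A scalar quantity sampled at every grid node."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @classmethod
    def full(cls, grid: GridSpec, value: float = 0.0) -> "ScalarField":
        return cls(grid, np.full(grid.shape, float(value)))

    @classmethod
    def from_function(cls, grid: GridSpec, fn) -> "ScalarField":
        X, Y = grid.coords()
        return cls(grid, np.asarray(fn(X, Y), dtype=float))

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy())

    def integral(self) -> float:
        """Trapezoid-free discrete integral: sum of nodes times cell area."""
        return float(self.values.sum() * self.grid.cell_area())


@dataclass
class VectorField:
    """Two scalar components (x, y) on the grid."""

    grid: GridSpec
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.grid.shape or self.y.shape != self.grid.shape:
            raise ValueError("vector component shape does not match grid")

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.x, self.y)


# --------------------------------------------------------------------------
# boundary policies

SideSpec = Union[str, Tuple[str, float]]


@dataclass(frozen=True)
class BoundaryPolicy:
    """Per-side ghost-node rule used by every stencil.

    Each side is ``"no-flux"`` (reflection through the half-point just
    outside the boundary node: ghost = boundary value, which makes every
    no-flux stencil exactly sum-conserving), ``"periodic"`` (wrap; must be
    set on both sides of an axis), or ``("dirichlet", value)`` (boundary
    node pinned; ghost by linear extrapolation through the pinned value).
    """

    left: SideSpec = "no-flux"
    right: SideSpec = "no-flux"
    bottom: SideSpec = "no-flux"
    top: SideSpec = "no-flux"

    def __post_init__(self) -> None:
        for side in (self.left, self.right, self.bottom, self.top):
            kind = side[0] if isinstance(side, tuple) else side
            if kind not in ("no-flux", "periodic", "dirichlet"):
                raise ValueError(f"unknown boundary kind {kind!r}")
        lp = _kind(self.left) == "periodic"
        rp = _kind(self.right) == "periodic"
        bp = _kind(self.bottom) == "periodic"
        tp = _kind(self.top) == "periodic"
        if lp != rp or bp != tp:
            raise ValueError("periodic boundaries must pair across an axis")


def _kind(side: SideSpec) -> str:
    return side[0] if isinstance(side, tuple) else side


def _value(side: SideSpec) -> float:
    return float(side[1]) if isinstance(side, tuple) else 0.0


NO_FLUX = BoundaryPolicy()
PERIODIC = BoundaryPolicy("periodic", "periodic", "periodic", "periodic")


def dirichlet(value: float = 0.0) -> BoundaryPolicy:
    d = ("dirichlet", float(value))
    return BoundaryPolicy(d, d, d, d)


def _pad(values: np.ndarray, bc: BoundaryPolicy) -> np.ndarray:
    """Return the (nx+2, ny+2) array with one ghost layer per the policy."""
    g = np.empty((values.shape[0] + 2, values.shape[1] + 2), dtype=float)
    g[1:-1, 1:-1] = values

    def ghost(side: SideSpec, interior: np.ndarray, wrap: np.ndarray, bnode: np.ndarray):
        k = _kind(side)
        if k == "no-flux":
            return bnode
        if k == "periodic":
            return wrap
        return 2.0 * _value(side) - interior  # dirichlet

    # x-axis ghosts (rows 0 and -1), computed on the interior columns
    g[0, 1:-1] = ghost(bc.left, values[1, :], values[-1, :], values[0, :])
    g[-1, 1:-1] = ghost(bc.right, values[-2, :], values[0, :], values[-1, :])
    # y-axis ghosts
    g[1:-1, 0] = ghost(bc.bottom, values[:, 1], values[:, -1], values[:, 0])
    g[1:-1, -1] = ghost(bc.top, values[:, -2], values[:, 0], values[:, -1])
    # corners: average of the two adjacent edge ghosts (only the mixed
    # derivative touches them, and only at boundary nodes)
    g[0, 0] = 0.5 * (g[0, 1] + g[1, 0])
    g[0, -1] = 0.5 * (g[0, -2] + g[1, -1])
    g[-1, 0] = 0.5 * (g[-1, 1] + g[-2, 0])
    g[-1, -1] = 0.5 * (g[-1, -2] + g[-2, -1])
    return g


# --------------------------------------------------------------------------
# stencils


def laplacian(f: ScalarField, bc: BoundaryPolicy = NO_FLUX) -> ScalarField:
    """Second-order 5-point Laplacian with ghost values set by ``bc``."""
    g = _pad(f.values, bc)
    h2 = f.grid.h * f.grid.h
    out = (
        g[2:, 1:-1] + g[:-2, 1:-1] + g[1:-1, 2:] + g[1:-1, :-2] - 4.0 * g[1:-1, 1:-1]
    ) / h2
    return ScalarField(f.grid, out)


def second_derivative(
    f: ScalarField, i: str, j: str, bc: BoundaryPolicy = NO_FLUX
) -> ScalarField:
    """Centered second derivative d^2 f / (d_i d_j), i, j in {"x", "y"}.

    Pure derivatives use the 3-point stencil; the mixed derivative uses the
    symmetric 4-point cross stencil, so ``d_xy == d_yx`` identically.
    """
    if i not in ("x", "y") or j not in ("x", "y"):
        raise ValueError(f"axes must be 'x' or 'y', got {i!r}, {j!r}")
    g = _pad(f.values, bc)
    h2 = f.grid.h * f.grid.h
    if i == j == "x":
        out = (g[2:, 1:-1] - 2.0 * g[1:-1, 1:-1] + g[:-2, 1:-1]) / h2
    elif i == j == "y":
        out = (g[1:-1, 2:] - 2.0 * g[1:-1, 1:-1] + g[1:-1, :-2]) / h2
    else:
        out = (g[2:, 2:] - g[2:, :-2] - g[:-2, 2:] + g[:-2, :-2]) / (4.0 * h2)
    return ScalarField(f.grid, out)


def gradient(f: ScalarField, bc: BoundaryPolicy = NO_FLUX) -> VectorField:
    """Centered first differences of ``f``; units of f per micrometre."""
    g = _pad(f.values, bc)
    h2 = 2.0 * f.grid.h
    gx = (g[2:, 1:-1] - g[:-2, 1:-1]) / h2
    gy = (g[1:-1, 2:] - g[1:-1, :-2]) / h2
    return VectorField(f.grid, gx, gy)


def divergence(v: VectorField, bc: BoundaryPolicy = NO_FLUX) -> ScalarField:
    gx = _pad(v.x, bc)
    gy = _pad(v.y, bc)
    h2 = 2.0 * v.grid.h
    out = (gx[2:, 1:-1] - gx[:-2, 1:-1]) / h2 + (gy[1:-1, 2:] - gy[1:-1, :-2]) / h2
    return ScalarField(v.grid, out)


# --------------------------------------------------------------------------
# disc averaging


def disc_kernel(radius: float, h: float) -> np.ndarray:
    """Boolean mask of grid offsets within Euclidean distance ``radius``."""
    n = int(np.floor(radius / h))
    dx = np.arange(-n, n + 1) * h
    DX, DY = np.meshgrid(dx, dx, indexing="ij")
    return (DX * DX + DY * DY) <= radius * radius + 1e-12


def disc_mean(f: ScalarField, radius: float) -> ScalarField:
    """Mean of ``f`` over the disc of ``radius`` micrometres at each node.

    Near the boundary the kernel is renormalized over in-domain nodes, so a
    constant field is reproduced exactly everywhere.
    """
    if radius < f.grid.h:
        raise ValueError(
            f"averaging radius {radius} below grid spacing {f.grid.h}"
        )
    kernel = disc_kernel(radius, f.grid.h).astype(float)
    num = ndimage.convolve(f.values, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(f.values), kernel, mode="constant", cval=0.0)
    return ScalarField(f.grid, num / den)
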