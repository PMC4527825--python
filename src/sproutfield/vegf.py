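"""VEGF transport: diffusion with consumption at the vessel.

The angiogenic factor obeys

    dV/dt = D_V * lap(V) - alpha_V * V * phi * Theta(phi)

with V = 1 held at the hypoxic (right) boundary and no-flux elsewhere.
Concentrations are relative to the hypoxic boundary, so V is dimensionless
and stays in [0, 1] at quasi-steady state.  Diffusion is fast compared with
cell movement, so the simulator uses the quasi-steady profile, refreshed at
tip-relocation events rather than co-stepped with phi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .grid import BoundaryPolicy, GridSpec, ScalarField, laplacian

__all__ = ["VEGFParams", "init_vegf", "step_vegf", "relax_vegf", "vegf_bc"]


@dataclass(frozen=True)
class VEGFParams:
    """Transport constants for the angiogenic factor.

    ``D_V`` is the tissue diffusion constant in um^2/hr (order 1e4, i.e.
    ~1e-7 cm^2/s) and ``alpha_V`` the consumption rate at confluent vessel
    in 1/hr.  Together they set the absorption length sqrt(D_V/alpha_V)
    (~14 um at the defaults), chosen so the quasi-steady level at the
    parental vessel is low but nonzero (~0.1 relative to the hypoxic
    boundary, the scale of the V_m = 0.05 proliferation trigger) and the
    concentration grades several-fold over one sprout length.  Only this
    relative profile feeds back on the model, through gradients and
    thresholds.
    """

    D_V: float = 36000.0
    alpha_V: float = 180.0
    V_boundary: float = 1.0

    def __post_init__(self) -> None:
        if self.D_V <= 0:
            raise ValueError("diffusion constant must be positive")
        if self.alpha_V < 0:
            raise ValueError("consumption rate must be non-negative")


def vegf_bc(params: VEGFParams) -> BoundaryPolicy:
    """No-flux everywhere except the hypoxic right boundary held at V=1."""
    return BoundaryPolicy(right=("dirichlet", params.V_boundary))


def init_vegf(grid: GridSpec, params: VEGFParams = VEGFParams()) -> ScalarField:
    """Linear ramp from 0 at the left boundary to V_boundary at the right."""
    X, _ = grid.coords()
    lx = grid.extent[0]
    return ScalarField(grid, params.V_boundary * (X - grid.origin[0]) / lx)


def stable_dt_vegf(grid: GridSpec, params: VEGFParams) -> float:
    """Largest explicit-Euler step for the diffusion operator, hours."""
    return grid.h**2 / (4.0 * params.D_V)


def step_vegf(
    V: ScalarField, phi: ScalarField, params: VEGFParams, dt: float
) -> ScalarField:
    """One explicit Euler step of the diffusion-consumption equation."""
    if dt > stable_dt_vegf(V.grid, params) * (1 + 1e-12):
        raise ValueError(
            f"dt={dt} exceeds the diffusion stability bound "
            f"{stable_dt_vegf(V.grid, params)}"
        )
    bc = vegf_bc(params)
    lap = laplacian(V, bc).values
    sink = params.alpha_V * V.values * np.maximum(phi.values, 0.0)
    out = V.values + dt * (params.D_V * lap - sink)
    out[-1, :] = params.V_boundary
    return ScalarField(V.grid, out)


def _noflux_1d(n: int) -> sparse.csr_matrix:
    """1-D second-difference operator with half-point reflection at both
    ends (ghost = boundary value), matching the grid module's stencils."""
    main = np.full(n, -2.0)
    main[0] = main[-1] = -1.0
    off = np.ones(n - 1)
    return sparse.diags([off, main, off], [-1, 0, 1], format="csr")


# cached per (grid, D_V): pinned diffusion operator and boundary mask
_LAP_CACHE: dict = {}


def _steady_operator(grid: GridSpec, phi: ScalarField, params: VEGFParams):
    """Sparse operator for D_V*lap(V) - alpha_V*max(phi,0)*V = 0 with the
    run's boundary policy (Dirichlet right, no-flux elsewhere).

    Only the sink diagonal changes between calls (phi moves); the diffusion
    part and the boundary pinning are cached per grid.
    """
    nx, ny = grid.nx, grid.ny
    n = nx * ny
    key = (nx, ny, grid.h, params.D_V)
    cached = _LAP_CACHE.get(key)
    if cached is None:
        lap = (
            sparse.kron(_noflux_1d(nx), sparse.identity(ny))
            + sparse.kron(sparse.identity(nx), _noflux_1d(ny))
        ) / grid.h**2
        free = np.ones(n)
        free[(nx - 1) * ny :] = 0.0  # hypoxic boundary rows, pinned
        base = (sparse.diags(free) @ (params.D_V * lap)).tocsr()
        base = base + sparse.diags(1.0 - free)
        _LAP_CACHE[key] = (base, free)
        cached = (base, free)
    base, free = cached
    sink = free * params.alpha_V * np.maximum(phi.values, 0.0).reshape(-1)
    A = base - sparse.diags(sink)
    b = (1.0 - free) * params.V_boundary
    return A.tocsr(), b


def relax_vegf(
    V: ScalarField,
    phi: ScalarField,
    params: VEGFParams,
    tol: float = 1e-3,
    method: str = "direct",
    max_iter: int = 200_000,
) -> ScalarField:
    """Quasi-steady VEGF profile for the current vessel configuration.

    ``method="direct"`` solves the linear steady problem in one sparse solve
    (the steady equation is linear in V, so the solution is unique and
    independent of the initial guess).  ``method="iterate"`` time-marches
    :func:`step_vegf` at the stability-limited dt until max|dV|/dt < tol
    (tol in 1/hr); both routes agree to the iteration tolerance.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if method == "direct":
        A, b = _steady_operator(V.grid, phi, params)
        sol = spsolve(A.tocsc(), b)
        return ScalarField(V.grid, sol.reshape(V.grid.shape))
    if method != "iterate":
        raise ValueError(f"unknown method {method!r}")
    dt = stable_dt_vegf(V.grid, params)
    cur = V
    for _ in range(max_iter):
        nxt = step_vegf(cur, phi, params, dt)
        res = np.abs(nxt.values - cur.values).max() / dt
        cur = nxt
        if res < tol:
            return cur
    raise RuntimeError(
        f"VEGF relaxation did not reach tol={tol} in {max_iter} iterations "
        f"(last residual {res:.3e}/hr)"
    )
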