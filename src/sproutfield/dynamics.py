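"""Coupled time evolution of the order parameter.

The capillary order parameter phi (+1 vessel, -1 ECM) follows conserved
interface dynamics driven by surface tension, the rigidity-mismatch term,
the adhesion/traction coupling, and the proliferation source:

    dphi/dt = M * { rho_phi * lap(-phi + phi^3 - eps^2 lap(phi))
                    - mu1 * lap( sum_ij (d_ij w)^2 - (lap w)^2 / d )
                    + (alpha/L0) * [ lap(chi_t) + 2 mu1 sum_ij d_ij(...) ] }
              + alpha_p

At every step w is obtained from the quasi-static Poisson relation; after
each t_cell interval the tip traction is re-centred on the sprout front and
the VEGF profile re-relaxed.  All flux terms are in divergence form, so
endothelial matter is conserved exactly up to the proliferation source.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .elasticity import (
    ElasticityParams,
    _eig_mirror,
    elastic_terms,
    solve_w,
    strain_measure,
)
from .grid import NO_FLUX, GridSpec, ScalarField, laplacian
from .morphology import measure
from .proliferation import ProliferationRule, alpha_p
from .tipcell import (
    SproutLostError,
    TipCell,
    TipSchedule,
    build_chi,
    interface_points,
    maybe_reposition,
)
from .vegf import VEGFParams, init_vegf, relax_vegf

__all__ = [
    "ModelParams",
    "RunConfig",
    "SimulationState",
    "Trajectory",
    "rhs_phi",
    "stable_dt",
    "step",
    "initial_state",
    "run",
]

# Mobility and free-energy density are fixed by reference behaviors rather
# than measured directly: M sits in the regime where the wall equilibrates
# within each tip-relocation interval (isolated detached cells then migrate
# at the few-um/hr pace that covers ~230 um over a multi-day explant assay),
# and rho_phi is set jointly with the rigidity contrast mu1 so that at peak
# traction 3.0 kPa a sprout stays intact through 14.5 hr at adhesion
# 0.31 kPa but breaks at 0.47 kPa (see docs/methods.md, "calibration").
DEFAULT_M = 45.0  # um^2 / (kPa hr)
DEFAULT_RHO_PHI = 0.58  # kPa


@dataclass(frozen=True)
class ModelParams:
    """The six dynamical parameters plus the three sub-models.

    ``M`` (um^2/kPa/hr) sets the timescale; ``rho_phi`` (kPa) balances
    surface tension against elasticity; ``epsilon`` (um) is the interface
    width, resolved by at least two grid cells; ``alpha`` (kPa) is the
    cell-cell adhesion coefficient (study range 0-1 kPa).
    """

    M: float = DEFAULT_M
    rho_phi: float = DEFAULT_RHO_PHI
    epsilon: float = 2.0
    alpha: float = 0.47
    elasticity: ElasticityParams = field(default_factory=ElasticityParams)
    vegf: VEGFParams = field(default_factory=VEGFParams)
    rule: ProliferationRule = field(default_factory=ProliferationRule)

    def __post_init__(self) -> None:
        if self.M <= 0 or self.rho_phi <= 0:
            raise ValueError("M and rho_phi must be positive")
        if self.alpha < 0:
            raise ValueError("adhesion coefficient must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("interface width must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Geometry, schedule and numerical knobs of one sprouting run."""

    grid: GridSpec = field(default_factory=lambda: GridSpec(131, 101, 1.0))
    params: ModelParams = field(default_factory=ModelParams)
    traction: float = 3.0  # kPa, peak tip traction
    tip_radius: float = 5.0  # um
    tip_anisotropy: str = "none"
    t_cell_min: float = 5.0
    vegf_refresh_every: int = 1  # tip relocations between VEGF re-relaxations
    search_radius: float = 15.0  # um
    split_persist_checks: int = 3  # consecutive t_cell checks to call a split
    vessel_width: float = 10.0  # um, initial slab
    initial_condition: str = "vessel"  # or "isolated_cell"
    cell_radius: float = 5.0  # um, isolated-cell initial condition
    t_end: float = 14.5  # hr
    save_every: float = 0.25  # hr, metrics sampling interval
    scheme: str = "semi-implicit"  # or "explicit"
    dt_safety: Optional[float] = None  # scheme default: 0.1 explicit, 0.25 imex
    dt_override: Optional[float] = None
    store_snapshots: bool = False
    max_abs_phi: float = 5.0  # divergence guard

    def __post_init__(self) -> None:
        if self.params.epsilon < 2.0 * self.grid.h - 1e-12:
            raise ValueError(
                f"interface width {self.params.epsilon} must span at least two "
                f"grid cells (h={self.grid.h})"
            )
        if self.traction < 0:
            raise ValueError("traction must be non-negative")
        if self.t_end <= 0 or self.save_every <= 0:
            raise ValueError("t_end and save_every must be positive")


@dataclass
class SimulationState:
    t: float
    phi: ScalarField
    V: ScalarField
    w: ScalarField
    chi_t: ScalarField
    tip: TipCell
    schedule: TipSchedule
    events: List[Tuple[float, str]] = field(default_factory=list)
    # consecutive relocation-cadence checks with more than one body; a split
    # is only declared once the disconnection persists (see step)
    split_streak: int = 0


@dataclass
class Trajectory:
    """Metrics time series plus events for one run."""

    config: RunConfig
    metrics: pd.DataFrame  # t_hr, length_um, n_components, max_width_um, parental_width_um
    events: List[Tuple[float, str]]
    tip_track: pd.DataFrame  # t_hr, x_um, y_um, amplitude_kpa
    final: SimulationState
    snapshots: List[Tuple[float, ScalarField]] = field(default_factory=list)

    @property
    def split_occurred(self) -> bool:
        return any(kind == "split_detected" for _, kind in self.events)

    @property
    def sprout_lost(self) -> bool:
        return any(kind == "sprout_lost" for _, kind in self.events)

    @property
    def broke(self) -> bool:
        """Breakage in any of its observable forms: a persistent multi-body
        state, the tip lost beyond the search radius, or the front collapsing
        after a shed head dissolves."""
        kinds = {kind for _, kind in self.events}
        return bool(kinds & {"split_detected", "sprout_lost", "front_collapse"})

    @property
    def final_length(self) -> float:
        return float(self.metrics["length_um"].iloc[-1])

    def front_velocity(self) -> pd.DataFrame:
        """Centred-difference front velocity (um/hr) from the length series."""
        t = self.metrics["t_hr"].to_numpy()
        ln = self.metrics["length_um"].to_numpy()
        v = np.gradient(ln, t)
        return pd.DataFrame({"t_hr": t, "velocity_um_hr": v})


# --------------------------------------------------------------------------
# right-hand side and time step


def rhs_phi(state: SimulationState, params: ModelParams) -> ScalarField:
    """Assemble the full dphi/dt for the current state (w must be consistent)."""
    full, _ = explicit_rhs_parts(state, params)
    if not np.all(np.isfinite(full)):
        raise FloatingPointError("non-finite right-hand side; state diverged")
    return ScalarField(state.phi.grid, full)


def stable_dt(params: ModelParams, grid: GridSpec, safety: float = 0.1) -> float:
    """Explicit-Euler step bound, hours.

    The fourth-order surface operator dominates: dt ~ safety*h^4/(8*M*rho_phi
    *eps^2).  The second-order elastic and double-well contributions add a
    diffusion-like cap h^2/(2*M*(3*rho_phi + mu1 + alpha)) that only binds
    for extreme elastic parameters.  The default safety of 0.1 was fixed by
    an empirical stability sweep at the reference resolution (larger factors
    blow up within the first simulated hour once the traction well deepens
    the local free-energy landscape).
    """
    h = grid.h
    dt4 = safety * h**4 / (8.0 * params.M * params.rho_phi * params.epsilon**2)
    coef2 = 3.0 * params.rho_phi + params.elasticity.mu1 + params.alpha
    dt2 = safety * h**2 / (2.0 * params.M * coef2)
    return min(dt4, dt2)


def imex_dt(params: ModelParams, grid: GridSpec, safety: float = 0.1) -> float:
    """Step bound for the semi-implicit scheme, hours.

    With the fourth-order operator implicit, the explicit double-well and
    elastic contributions limit the step like a second-order diffusion:
    dt ~ safety * h^2 / (M * (3*rho_phi + mu1 + alpha)).  The same safety
    default as :func:`stable_dt` keeps ~2x margin at the calibration point.
    """
    coef2 = 3.0 * params.rho_phi + params.elasticity.mu1 + params.alpha
    return safety * grid.h**2 / (params.M * coef2)


# cached eigenbasis of the all-mirror (no-flux) Laplacian used by the
# semi-implicit scheme; keyed per grid
_IMEX_CACHE: dict = {}


def _imex_basis(grid: GridSpec):
    key = (grid.nx, grid.ny, grid.h)
    out = _IMEX_CACHE.get(key)
    if out is None:
        lx, Vx = _eig_mirror(grid.nx, True, True)
        ly, Vy = _eig_mirror(grid.ny, True, True)
        lam = (lx[:, None] + ly[None, :]) / grid.h**2  # eigenvalues of lap
        out = (Vx, Vy, lam)
        _IMEX_CACHE[key] = out
    return out


def explicit_rhs_parts(state: SimulationState, params: ModelParams):
    """(full rhs, rhs without the implicit eps^2 biharmonic part)."""
    phi, w, chi = state.phi, state.w, state.chi_t
    eps2 = params.epsilon**2
    lap_phi = laplacian(phi, NO_FLUX)
    bulk = ScalarField(phi.grid, -phi.values + phi.values**3)
    surf_bulk = params.rho_phi * laplacian(bulk, NO_FLUX).values
    surf_eps = -params.rho_phi * eps2 * laplacian(
        ScalarField(phi.grid, lap_phi.values), NO_FLUX
    ).values
    quad, coupling = elastic_terms(phi, w, chi, params.alpha, params.elasticity)
    s = strain_measure(phi, chi, params.alpha)
    growth = alpha_p(phi, state.V, s, params.rule)
    explicit = params.M * (surf_bulk - quad + coupling) + growth.values
    full = explicit + params.M * surf_eps
    return full, explicit


def _advance_phi(state: SimulationState, config: RunConfig, dt: float) -> ScalarField:
    """One time step of phi: explicit Euler or the semi-implicit scheme.

    The semi-implicit scheme treats the stiff fourth-order surface operator
    (M*rho_phi*eps^2*lap(lap(phi))) implicitly in the mirror-Laplacian
    eigenbasis and everything else (double-well, elastic, proliferation)
    explicitly; it conserves endothelial matter exactly like the explicit
    scheme (the implicit factor is 1 on the constant mode) and converges to
    the same dynamics as dt -> 0.
    """
    params = config.params
    full, explicit = explicit_rhs_parts(state, params)
    if not np.all(np.isfinite(full)):
        raise FloatingPointError("non-finite right-hand side; state diverged")
    if config.scheme == "explicit":
        return ScalarField(state.phi.grid, state.phi.values + dt * full)
    grid = state.phi.grid
    Vx, Vy, lam = _imex_basis(grid)
    target = state.phi.values + dt * explicit
    tt = Vx.T @ target @ Vy
    tt /= 1.0 + dt * params.M * params.rho_phi * params.epsilon**2 * lam**2
    out = Vx @ tt @ Vy.T
    return ScalarField(grid, out)


def step(state: SimulationState, config: RunConfig, dt: float) -> SimulationState:
    """Advance one step; relocate the tip when t_cell elapses."""
    params = config.params
    if config.scheme == "explicit" and dt > stable_dt(
        params, config.grid, config.dt_safety or 0.1
    ) * (1 + 1e-9):
        raise ValueError("dt exceeds the stability bound")

    w = solve_w(state.phi, state.chi_t, params.alpha, params.elasticity)
    state = replace_state(state, w=w)
    phi = _advance_phi(state, config, dt)
    if np.abs(phi.values).max() > config.max_abs_phi:
        raise FloatingPointError(
            f"|phi| exceeded {config.max_abs_phi}; the run diverged"
        )
    t = state.t + dt
    new = SimulationState(
        t, phi, state.V, w, state.chi_t, state.tip, state.schedule,
        state.events, state.split_streak,
    )
    if new.schedule.due(t):
        # Persistence-gated split detection: a momentary interface pinch at
        # the neck can re-heal within one or two relocation intervals; real
        # breakage (a tip cell that separates and migrates on) stays
        # disconnected.  Only a streak of multi-body checks counts.
        if _count_bodies(phi) > 1:
            new.split_streak += 1
        else:
            new.split_streak = 0
        if new.split_streak >= config.split_persist_checks and not any(
            k == "split_detected" for _, k in new.events
        ):
            new.events.append((t, "split_detected"))
        tip, schedule, moved = maybe_reposition(
            t, new.tip, new.schedule, phi, new.V, config.search_radius
        )
        if moved:
            chi = build_chi(tip, config.grid)
            n_reloc = sum(1 for _, k in new.events if k == "tip_relocated")
            if n_reloc % max(config.vegf_refresh_every, 1) == 0:
                V = relax_vegf(new.V, phi, params.vegf)
            else:
                V = new.V
            new = SimulationState(
                t, phi, V, w, chi, tip, schedule, new.events, new.split_streak
            )
            new.events.append((t, "tip_relocated"))
    return new


def _count_bodies(phi: ScalarField) -> int:
    """Connected endothelial bodies above the half-cell speck filter; cheap
    split check run at the tip-relocation cadence so that transient
    pinch-offs (detached cells that later shrink) are not missed between
    metrics samples."""
    return measure(phi, phi.grid.origin[0]).n_components


def replace_state(state: SimulationState, **kw) -> SimulationState:
    d = dict(
        t=state.t, phi=state.phi, V=state.V, w=state.w, chi_t=state.chi_t,
        tip=state.tip, schedule=state.schedule, events=state.events,
    )
    d.update(kw)
    return SimulationState(**d)


# --------------------------------------------------------------------------
# initialisation and the full run


def initial_phi(config: RunConfig) -> ScalarField:
    """Initial endothelial configuration.

    ``"vessel"``: vertical slab against the left boundary, tanh interface.
    ``"isolated_cell"``: a single detached cell (disc of ``cell_radius``)
    centred at x = vessel_width + cell_radius, mid-height — the configuration
    used to calibrate the mobility against observed single-cell migration.
    """
    grid = config.grid
    X, Y = grid.coords()
    eps = config.params.epsilon
    if config.initial_condition == "vessel":
        vals = np.tanh(
            (config.vessel_width + grid.origin[0] - X) / (np.sqrt(2.0) * eps)
        )
    elif config.initial_condition == "isolated_cell":
        cx = grid.origin[0] + config.vessel_width + config.cell_radius
        cy = grid.origin[1] + grid.extent[1] / 2.0
        r = np.hypot(X - cx, Y - cy)
        vals = np.tanh((config.cell_radius - r) / (np.sqrt(2.0) * eps))
    else:
        raise ValueError(f"unknown initial condition {config.initial_condition!r}")
    return ScalarField(grid, vals)


def initial_state(config: RunConfig) -> SimulationState:
    """Slab vessel, relaxed VEGF ramp, tip at the vessel's right interface."""
    grid = config.grid
    params = config.params
    phi = initial_phi(config)
    V = relax_vegf(init_vegf(grid, params.vegf), phi, params.vegf)

    # tip: interface point nearest the domain's horizontal midline in y,
    # most advanced toward the VEGF source (largest x) among ties
    pts = interface_points(phi)
    if pts.shape[0] == 0:
        raise ValueError("initial vessel has no interface")
    y_mid = grid.origin[1] + grid.extent[1] / 2.0
    best = pts[np.lexsort((-pts[:, 0], np.abs(pts[:, 1] - y_mid)))][0]
    tip = TipCell(
        center=(float(best[0]), float(best[1])),
        direction=(1.0, 0.0),
        amplitude=config.traction,
        radius=config.tip_radius,
        anisotropy=config.tip_anisotropy,
    )
    chi = build_chi(tip, grid)
    w = solve_w(phi, chi, params.alpha, params.elasticity)
    schedule = TipSchedule(config.t_cell_min, 0.0)
    return SimulationState(0.0, phi, V, w, chi, tip, schedule, [])


def run(config: RunConfig) -> Trajectory:
    """Advance the coupled system to t_end, sampling sprout metrics.

    Split events are detected on the metrics sampling grid; when the tip is
    lost (no interface within the search radius) the run records the event
    and returns the partial trajectory.
    """
    state = initial_state(config)
    baseline = config.vessel_width + config.grid.origin[0]
    if config.dt_override:
        dt = config.dt_override
    elif config.scheme == "explicit":
        dt = stable_dt(config.params, config.grid, config.dt_safety or 0.1)
    else:
        dt = imex_dt(config.params, config.grid, config.dt_safety or 0.25)
    dt = min(dt, TipSchedule(config.t_cell_min).t_cell_hr)

    rows: List[dict] = []
    tips: List[dict] = []
    snaps: List[Tuple[float, ScalarField]] = []

    peak_length = 0.0

    def sample(s: SimulationState) -> None:
        nonlocal peak_length
        m = measure(s.phi, baseline)
        # front collapse: a sprout that loses more than half of its peak
        # advance has shed its head (which then dissolved) — the breakage
        # signature when the detached cell is too small to persist
        if (
            peak_length > 10.0
            and m.length < 0.5 * peak_length
            and not any(k == "front_collapse" for _, k in s.events)
        ):
            s.events.append((s.t, "front_collapse"))
        peak_length = max(peak_length, m.length)
        rows.append(
            dict(
                t_hr=s.t,
                length_um=m.length,
                n_components=m.n_components,
                max_width_um=m.max_width,
                parental_width_um=m.parental_width,
            )
        )
        tips.append(
            dict(t_hr=s.t, x_um=s.tip.center[0], y_um=s.tip.center[1],
                 amplitude_kpa=s.tip.amplitude)
        )
        if config.store_snapshots:
            snaps.append((s.t, s.phi.copy()))

    sample(state)
    next_sample = config.save_every
    try:
        while state.t < config.t_end - 1e-9:
            this_dt = min(dt, config.t_end - state.t)
            state = step(state, config, this_dt)
            if state.t >= next_sample - 1e-9:
                sample(state)
                next_sample += config.save_every
    except SproutLostError:
        state.events.append((state.t, "sprout_lost"))
        sample(state)

    if rows[-1]["t_hr"] < state.t - 1e-9:
        sample(state)
    return Trajectory(
        config=config,
        metrics=pd.DataFrame(rows),
        events=list(state.events),
        tip_track=pd.DataFrame(tips),
        final=state,
        snapshots=snaps,
    )
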