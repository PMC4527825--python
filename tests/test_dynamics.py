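"""Time stepper: right-hand-side oracle, conservation bookkeeping, stability
bound scalings, scheme equivalence, and run-level behavior on short horizons."""

import numpy as np
import pytest

from sproutfield.dynamics import (
    ModelParams,
    RunConfig,
    SimulationState,
    Trajectory,
    imex_dt,
    initial_phi,
    initial_state,
    rhs_phi,
    run,
    stable_dt,
    step,
)
from sproutfield.elasticity import (
    elastic_coupling_term,
    elastic_quadratic_term,
    solve_w,
    strain_measure,
)
from sproutfield.fixtures import make_fixture
from sproutfield.grid import NO_FLUX, GridSpec, ScalarField, laplacian
from sproutfield.proliferation import ProliferationRule, Scenario, alpha_p
from sproutfield.tipcell import TipCell, TipSchedule


def small_config(**kw) -> RunConfig:
    kw.setdefault("grid", GridSpec(64, 51, 2.0))
    kw.setdefault("params", ModelParams(epsilon=4.0))
    kw.setdefault("t_end", 0.5)
    kw.setdefault("save_every", 0.25)
    return RunConfig(**kw)


def state_from(phi, config, rule=None):
    params = config.params
    from sproutfield.tipcell import build_chi
    from sproutfield.vegf import init_vegf

    lx, ly = config.grid.extent
    tip = TipCell(
        center=(config.grid.origin[0] + lx / 2, config.grid.origin[1] + ly / 2),
        amplitude=config.traction,
    )
    chi = build_chi(tip, config.grid)
    w = solve_w(phi, chi, params.alpha, params.elasticity)
    V = init_vegf(config.grid)
    return SimulationState(0.0, phi, V, w, chi, tip, TipSchedule(5.0, 0.0), [])


class TestRhsPhi:
    def test_uniform_bulk_phase_is_stationary_without_forces(self):
        g = GridSpec(32, 32, 1.0)
        params = ModelParams(epsilon=2.0, alpha=0.0)
        cfg = RunConfig(grid=g, params=params, traction=0.0)
        phi = ScalarField.full(g, 1.0)
        st = state_from(phi, cfg)
        out = rhs_phi(st, params)
        assert np.abs(out.values).max() < 1e-10

    def test_equilibrium_kink_is_stationary_to_stencil_error(self):
        """The 1-D tanh profile solves eps^2 phi'' = phi^3 - phi exactly; on
        the grid the residual is pure discretization error, vanishing ~h^2."""
        errs = []
        for h in (1.0, 0.5):
            n = int(64 / h) + 1
            g = GridSpec(n, 9, h)
            params = ModelParams(epsilon=4.0, alpha=0.0)
            cfg = RunConfig(grid=g, params=params, traction=0.0)
            phi = make_fixture("kink_1d", g, epsilon=4.0)
            st = state_from(phi, cfg)
            out = rhs_phi(st, params)
            errs.append(np.abs(out.values[2:-2, 2:-2]).max())
        assert errs[0] > 3.0 * errs[1]  # ~h^2 decay
        assert errs[1] < 0.05 * params.M * params.rho_phi

    def test_matches_term_by_term_assembly(self):
        """Independent oracle: reassemble the right-hand side from the public
        per-term operations and the proliferation source."""
        g = GridSpec(16, 16, 1.0)
        params = ModelParams(
            epsilon=2.0, alpha=0.31,
            rule=ProliferationRule(Scenario.VEGF, M_P=0.5, L_V=0.5),
        )
        cfg = RunConfig(grid=g, params=params)
        phi = make_fixture("random_smooth", g, seed=50)
        st = state_from(phi, cfg)

        lap_phi = laplacian(st.phi, NO_FLUX)
        mu = ScalarField(
            g,
            -st.phi.values + st.phi.values**3
            - params.epsilon**2 * lap_phi.values,
        )
        surface = params.rho_phi * laplacian(mu, NO_FLUX).values
        quad = elastic_quadratic_term(st.w, params.elasticity).values
        coup = elastic_coupling_term(
            st.phi, st.w, st.chi_t, params.alpha, params.elasticity
        ).values
        s = strain_measure(st.phi, st.chi_t, params.alpha)
        growth = alpha_p(st.phi, st.V, s, params.rule).values
        oracle = params.M * (surface - quad + coup) + growth

        out = rhs_phi(st, params).values
        assert np.abs(out - oracle).max() < 1e-10


class TestStableDt:
    def test_h4_scaling(self):
        # wide interface keeps the fourth-order branch binding at both h
        p = ModelParams(epsilon=8.0)
        a = stable_dt(p, GridSpec(32, 32, 2.0))
        b = stable_dt(p, GridSpec(32, 32, 1.0))
        assert np.isclose(a / b, 16.0)

    def test_inverse_in_mobility(self):
        g = GridSpec(32, 32, 2.0)
        a = stable_dt(ModelParams(M=45.0), g)
        b = stable_dt(ModelParams(M=90.0), g)
        assert np.isclose(a / b, 2.0)

    def test_imex_step_larger_than_explicit(self):
        g = GridSpec(64, 51, 1.0)
        p = ModelParams()
        assert imex_dt(p, g) > 2.0 * stable_dt(p, g)

    def test_explicit_step_rejects_oversized_dt(self):
        cfg = small_config(scheme="explicit")
        st = initial_state(cfg)
        with pytest.raises(ValueError):
            step(st, cfg, 10.0 * stable_dt(cfg.params, cfg.grid))


class TestConservation:
    def test_matter_conserved_without_proliferation_or_traction(self):
        """No source terms: the discrete integral of phi drifts by < 1e-6
        relative over 100 steps (all flux terms are divergences)."""
        cfg = small_config(traction=0.0)
        st = initial_state(cfg)
        dt = imex_dt(cfg.params, cfg.grid, 0.25)
        total0 = st.phi.values.sum()
        for _ in range(100):
            st = step(st, cfg, dt)
        drift = abs(st.phi.values.sum() - total0) / abs(total0)
        assert drift < 1e-6

    def test_growth_matches_integrated_proliferation_source(self):
        """With proliferation on, d/dt of the phi integral equals the alpha_p
        integral (bookkeeping of the only non-conservative term)."""
        rule = ProliferationRule(Scenario.VEGF, M_P=0.5, L_V=0.2)
        cfg = small_config(
            traction=0.0,
            params=ModelParams(epsilon=4.0, rule=rule),
        )
        st = initial_state(cfg)
        dt = imex_dt(cfg.params, cfg.grid, 0.25)
        total0 = st.phi.values.sum()
        source = 0.0
        for _ in range(60):
            s = strain_measure(st.phi, st.chi_t, cfg.params.alpha)
            source += dt * alpha_p(st.phi, st.V, s, rule).values.sum()
            st = step(st, cfg, dt)
        growth = st.phi.values.sum() - total0
        assert source > 0
        assert abs(growth - source) < 0.01 * source


class TestSchemes:
    def test_semi_implicit_matches_explicit_at_matched_dt(self):
        dt = stable_dt(ModelParams(epsilon=4.0), GridSpec(64, 51, 2.0))
        out = {}
        for scheme in ("explicit", "semi-implicit"):
            cfg = small_config(scheme=scheme, dt_override=dt, t_end=0.3)
            out[scheme] = run(cfg).final.phi.values
        diff = np.abs(out["explicit"] - out["semi-implicit"]).max()
        assert diff < 5e-3  # first-order-in-dt splitting difference

    def test_divergence_guard_aborts(self):
        cfg = small_config(max_abs_phi=1.001)
        st = initial_state(cfg)
        with pytest.raises(FloatingPointError):
            for _ in range(200):
                st = step(st, cfg, imex_dt(cfg.params, cfg.grid, 0.25))


class TestRun:
    def test_zero_traction_produces_no_elongation(self):
        cfg = small_config(traction=0.0, t_end=2.0, save_every=0.5)
        traj = run(cfg)
        assert traj.metrics["length_um"].max() < 2.0
        assert not traj.split_occurred

    def test_initial_vessel_slab_geometry(self):
        cfg = small_config()
        phi = initial_phi(cfg)
        assert phi.values[0, :].min() > 0.9  # vessel at the left wall
        assert phi.values[-1, :].max() < -0.9
        # interface mid-crossing near the slab width
        sign_change = np.nonzero(np.diff(np.sign(phi.values[:, 25])))[0][0]
        assert abs(sign_change * cfg.grid.h - cfg.vessel_width) <= cfg.grid.h

    def test_isolated_cell_initial_condition(self):
        cfg = small_config(initial_condition="isolated_cell")
        phi = initial_phi(cfg)
        assert phi.values.max() > 0.5  # the cell exists
        assert phi.values[0, :].max() < 0.0  # detached from the wall

    def test_metrics_sampled_on_schedule_and_monotone_time(self):
        cfg = small_config(t_end=1.0, save_every=0.25)
        traj = run(cfg)
        t = traj.metrics["t_hr"].to_numpy()
        assert t[0] == 0.0
        assert np.all(np.diff(t) > 0)
        assert abs(t[-1] - 1.0) < 1e-6
        assert len(traj.tip_track) == len(traj.metrics)

    def test_deterministic_replay(self):
        cfg = small_config(t_end=0.5)
        a = run(cfg)
        b = run(cfg)
        assert a.metrics.equals(b.metrics)
        assert np.array_equal(a.final.phi.values, b.final.phi.values)
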