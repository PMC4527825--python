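"""Parameter sweeps and transition finding.

Drivers for the three study planes: sprout length over traction x adhesion
without proliferation, morphology over M_P x limit (strain or VEGF) for each
regulation scenario, and bisection for the critical proliferation rate at
which breakage stops.  Sampling is the only source of randomness — each
individual run is deterministic — and every sweep carries a manifest
sufficient to replay it row by row.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .dynamics import ModelParams, RunConfig, Trajectory, run
from .grid import GridSpec
from .morphology import ClassifyThresholds, classify
from .proliferation import ProliferationRule, Scenario

__all__ = [
    "SweepConfig",
    "sweep_fig2",
    "sweep_proliferation",
    "find_critical_MP",
    "coarse_run_config",
]


def coarse_run_config(**overrides) -> RunConfig:
    """Desk-scale run used by the sweeps: 2 um cells on a 160x100 um domain.

    Roughly 25x cheaper than the reference resolution.  The interface width
    doubles to stay resolved, so the surface tension and drive constants are
    re-compensated (rho_phi 0.3, mu1 4.5) to preserve the reference-grid
    behavior at the study point: intact sprout at adhesion 0.31 kPa, tip
    breakage at 0.47 kPa, peak traction 3.0 kPa.  VEGF is refreshed every
    third tip relocation.
    """
    from .elasticity import ElasticityParams

    params = overrides.pop("params", None) or ModelParams(
        epsilon=4.0, rho_phi=0.3, elasticity=ElasticityParams(mu1=4.5)
    )
    return RunConfig(
        grid=overrides.pop("grid", GridSpec(81, 51, 2.0)),
        params=params,
        save_every=overrides.pop("save_every", 0.5),
        vegf_refresh_every=overrides.pop("vegf_refresh_every", 3),
        **overrides,
    )


@dataclass(frozen=True)
class SweepConfig:
    """One sweep: the parameter plane, its ranges, and how it is sampled.

    ``plane`` is ``"traction-adhesion"`` (random sampling, no proliferation),
    ``"mp-ls"`` or ``"mp-lv"`` (regular grids over maximum proliferation rate
    against limit strain / limit VEGF).
    """

    plane: str = "traction-adhesion"
    scenario: Scenario = Scenario.NONE
    n: int = 64
    seed: int = 0
    grid_shape: Tuple[int, int] = (6, 6)
    traction_range: Tuple[float, float] = (0.0, 6.0)  # kPa
    adhesion_range: Tuple[float, float] = (0.0, 1.0)  # kPa
    mp_range: Tuple[float, float] = (0.05, 0.8)  # 1/hr
    limit_range: Tuple[float, float] = (0.05, 1.0)  # kPa or relative V
    base_traction: float = 3.0  # kPa, fixed for proliferation planes
    base_adhesion: float = 0.47  # kPa, fixed for proliferation planes

    def manifest(self) -> Dict:
        d = asdict(self)
        d["scenario"] = Scenario(self.scenario).value
        return d


def _base_config(config_factory) -> RunConfig:
    return config_factory() if callable(config_factory) else config_factory


def sweep_fig2(
    sweep: SweepConfig,
    config_factory=coarse_run_config,
) -> pd.DataFrame:
    """Sprout length and breakage over randomly sampled traction x adhesion.

    Each sampled pair runs to t_end without proliferation; the table records
    the final length and whether the sprout split.  Individual run failures
    are recorded (status column) and do not stop the sweep.
    """
    rng = np.random.default_rng(sweep.seed)
    tractions = rng.uniform(*sweep.traction_range, size=sweep.n)
    adhesions = rng.uniform(*sweep.adhesion_range, size=sweep.n)
    rows = []
    for k, (tr, ad) in enumerate(zip(tractions, adhesions)):
        base = _base_config(config_factory)
        cfg = replace(
            base,
            traction=float(tr),
            params=replace(base.params, alpha=float(ad), rule=ProliferationRule()),
        )
        row = dict(run=k, traction_kpa=float(tr), adhesion_kpa=float(ad))
        try:
            traj = run(cfg)
            row.update(
                final_length_um=traj.final_length,
                split=bool(traj.broke),
                status="ok",
            )
        except (FloatingPointError, RuntimeError) as exc:  # pragma: no cover
            row.update(final_length_um=np.nan, split=True, status=f"failed: {exc}")
        rows.append(row)
    return pd.DataFrame(rows)


def _rule_for(sweep: SweepConfig, mp: float, limit: float) -> ProliferationRule:
    sc = Scenario(sweep.scenario)
    if sc in (Scenario.STRAIN, Scenario.STRAIN_VEGF_TRIGGER):
        return ProliferationRule(scenario=sc, M_P=mp, L_S=limit)
    return ProliferationRule(scenario=sc, M_P=mp, L_V=limit)


def run_classified(
    cfg: RunConfig, thresholds: ClassifyThresholds = ClassifyThresholds()
) -> Tuple[Trajectory, str]:
    traj = run(cfg)
    return traj, classify(traj, thresholds).label


# Classification thresholds compensated to the coarse preset's scale: the
# fat interface (eps = 4 um) roughly halves sprout lengths (slow cut-off 60
# -> 30 um) and widens the proliferating wall band, so every scenario shows
# baseline parental growth and all sprouts share the same smooth taper.  At
# this resolution the triangular back-widening of strain-regulated runs
# reads as intermediate parental growth (ratio 2.5-5.5, -> deformed), while
# only the area-wise interior proliferation of the VEGF-graded mode exceeds
# 5.5x (-> thick_parental); the shape-based taper/bulge tests are disabled
# (they cannot discriminate at this interface width).
COARSE_THRESHOLDS = ClassifyThresholds(
    slow_length=30.0,
    thick_ratio=5.5,
    taper_ratio=8.0,
    bulge_ratio=8.0,
    deformed_parental_ratio=2.5,
)


def sweep_proliferation(
    sweep: SweepConfig,
    config_factory=coarse_run_config,
    thresholds: ClassifyThresholds = COARSE_THRESHOLDS,
) -> pd.DataFrame:
    """Morphology class on a regular M_P x limit grid for one scenario.

    Traction and adhesion are pinned at the sweep's base values (3.0 and
    0.47 kPa in the breaking regime; 0.31 kPa for the low-adhesion variant).
    Default thresholds are the coarse-preset-compensated ones; pass explicit
    :class:`ClassifyThresholds` when sweeping at reference resolution.
    """
    n1, n2 = sweep.grid_shape
    mps = np.linspace(*sweep.mp_range, n1)
    limits = np.linspace(*sweep.limit_range, n2)
    limit_name = (
        "L_S" if Scenario(sweep.scenario) in (Scenario.STRAIN, Scenario.STRAIN_VEGF_TRIGGER)
        else "L_V"
    )
    rows = []
    for mp in mps:
        for lim in limits:
            base = _base_config(config_factory)
            cfg = replace(
                base,
                traction=sweep.base_traction,
                params=replace(
                    base.params,
                    alpha=sweep.base_adhesion,
                    rule=_rule_for(sweep, float(mp), float(lim)),
                ),
            )
            row = {"M_P_hr": float(mp), limit_name: float(lim)}
            try:
                _, label = run_classified(cfg, thresholds)
                row.update(label=label, status="ok")
            except (FloatingPointError, RuntimeError) as exc:  # pragma: no cover
                row.update(label="failed", status=f"failed: {exc}")
            rows.append(row)
    return pd.DataFrame(rows)


def find_critical_MP(
    scenario: Scenario,
    L_fixed: float,
    bracket: Tuple[float, float] = (0.0, 1.0),
    tol: float = 0.05,
    config_factory=coarse_run_config,
    base_traction: float = 3.0,
    base_adhesion: float = 0.47,
) -> Dict:
    """Bisect the maximum proliferation rate at the split/intact transition.

    The bracket must straddle the transition: breakage at the low end,
    intact sprout at the high end.  Returns the boundary M_P (midpoint of
    the final bracket) plus the evaluation log.
    """
    sweep = SweepConfig(scenario=scenario)

    def splits(mp: float) -> bool:
        base = _base_config(config_factory)
        cfg = replace(
            base,
            traction=base_traction,
            params=replace(
                base.params,
                alpha=base_adhesion,
                rule=_rule_for(sweep, mp, L_fixed),
            ),
        )
        return run(cfg).broke

    lo, hi = bracket
    log = []
    s_lo, s_hi = splits(lo), splits(hi)
    log += [(lo, s_lo), (hi, s_hi)]
    if not s_lo or s_hi:
        raise ValueError(
            f"bracket {bracket} does not straddle the transition "
            f"(split at lo: {s_lo}, split at hi: {s_hi})"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        s_mid = splits(mid)
        log.append((mid, s_mid))
        if s_mid:
            lo = mid
        else:
            hi = mid
    return dict(critical_MP=0.5 * (lo + hi), bracket=(lo, hi), log=log)
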