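"""Mechanoregulated endothelial proliferation source.

Four regulation scenarios are compared: rate ramping with local strain
(optionally gated by a VEGF trigger) and rate ramping with VEGF concentration
(optionally gated by a strain trigger).  The pointwise rate is generated only
by endothelial matter (phi > 0) and then averaged over a cell-sized disc, so
the source term alpha_p is the mean proliferation of the cell occupying each
point.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .grid import ScalarField, disc_mean

__all__ = ["Scenario", "ProliferationRule", "pointwise_rate", "alpha_p"]


class Scenario(str, Enum):
    """How strain and VEGF regulate the stalk-cell proliferation rate."""

    STRAIN = "strain"
    STRAIN_VEGF_TRIGGER = "strain+vegf-trigger"
    VEGF = "vegf"
    VEGF_STRAIN_TRIGGER = "vegf+strain-trigger"
    NONE = "none"


@dataclass(frozen=True)
class ProliferationRule:
    """Scenario plus its thresholds.

    ``M_P`` is the maximum proliferation rate (1/hr); the rate ramps linearly
    with strain up to the limit strain ``L_S`` (kPa) or with VEGF up to the
    limit concentration ``L_V``.  ``V_m`` and ``S_m`` are the trigger
    cut-offs (0.05 relative VEGF and 0.05 kPa strain respectively);
    ``R_cell`` is the averaging radius, one endothelial-cell radius.
    """

    scenario: Scenario = Scenario.NONE
    M_P: float = 0.0
    L_S: float = 0.5
    L_V: float = 0.5
    V_m: float = 0.05
    S_m: float = 0.05
    R_cell: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario", Scenario(self.scenario))
        if self.M_P < 0:
            raise ValueError("maximum proliferation rate must be non-negative")
        if self.scenario in (Scenario.STRAIN, Scenario.STRAIN_VEGF_TRIGGER) and self.L_S <= 0:
            raise ValueError("limit strain must be positive for strain scenarios")
        if self.scenario in (Scenario.VEGF, Scenario.VEGF_STRAIN_TRIGGER) and self.L_V <= 0:
            raise ValueError("limit VEGF must be positive for VEGF scenarios")
        if self.V_m < 0 or self.S_m < 0:
            raise ValueError("trigger cut-offs must be non-negative")


def pointwise_rate(
    V: ScalarField, s: ScalarField, rule: ProliferationRule
) -> ScalarField:
    """Local proliferation rate before disc averaging, 1/hr."""
    if V.grid != s.grid:
        raise ValueError("V and s must share a grid")
    sc = rule.scenario
    if sc is Scenario.NONE or rule.M_P == 0.0:
        return ScalarField(V.grid, np.zeros(V.grid.shape))
    if sc in (Scenario.STRAIN, Scenario.STRAIN_VEGF_TRIGGER):
        lam = rule.M_P * np.clip(s.values / rule.L_S, 0.0, 1.0)
        lam = np.where(s.values > 0.0, lam, 0.0)
        if sc is Scenario.STRAIN_VEGF_TRIGGER:
            lam = np.where(V.values > rule.V_m, lam, 0.0)
    else:
        lam = rule.M_P * np.clip(V.values / rule.L_V, 0.0, 1.0)
        if sc is Scenario.VEGF_STRAIN_TRIGGER:
            lam = np.where(s.values > rule.S_m, lam, 0.0)
    return ScalarField(V.grid, lam)


def alpha_p(
    phi: ScalarField,
    V: ScalarField,
    s: ScalarField,
    rule: ProliferationRule,
    gate_after_average: bool = False,
) -> ScalarField:
    """Proliferation source: disc mean of the endothelial-gated local rate.

    Rates are generated only where phi > 0 and averaged over the disc of
    radius ``R_cell``, so 0 <= alpha_p <= M_P everywhere and the source
    vanishes wherever the neighbourhood holds no endothelial matter.  With
    ``gate_after_average`` the Theta(phi) gate is applied to the averaged
    field instead (sensitivity variant).
    """
    rate = pointwise_rate(V, s, rule)
    gate = (phi.values > 0.0).astype(float)
    if rule.scenario is Scenario.NONE or rule.M_P == 0.0:
        return rate
    if gate_after_average:
        avg = disc_mean(rate, rule.R_cell)
        return ScalarField(phi.grid, avg.values * gate)
    gated = ScalarField(phi.grid, rate.values * gate)
    return disc_mean(gated, rule.R_cell)
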