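"""Configuration parsing and validation.

Runs are configured from a YAML file whose sections mirror the parameter
dataclasses; key names carry their units (``*_kpa``, ``*_um``, ``*_hr``,
``*_min``) to prevent unit drift between kPa, micrometres, hours and
minutes.  Unknown keys are rejected, and all validation errors in a file are
reported together.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Any, Dict, List

import yaml

from .dynamics import ModelParams, RunConfig
from .elasticity import ElasticityParams
from .grid import GridSpec
from .proliferation import ProliferationRule, Scenario
from .vegf import VEGFParams

__all__ = ["load_config", "save_config", "config_to_dict", "ConfigError"]


class ConfigError(ValueError):
    """One or more invalid/unknown configuration keys (all listed)."""


_GRID_KEYS = {"nx": "nx", "ny": "ny", "h_um": "h"}
_MODEL_KEYS = {
    "mobility_um2_per_kpa_hr": "M",
    "rho_phi_kpa": "rho_phi",
    "epsilon_um": "epsilon",
    "adhesion_kpa": "alpha",
}
_ELASTIC_KEYS = {
    "ecm_young_kpa": "ecm_young",
    "ecm_poisson": "ecm_poisson",
    "vessel_rigidity_fraction": "vessel_rigidity_fraction",
    "L0_kpa": "L0",
    "mu1_kpa": "mu1",
}
_VEGF_KEYS = {
    "diffusion_um2_hr": "D_V",
    "consumption_hr": "alpha_V",
    "boundary_value": "V_boundary",
}
_RULE_KEYS = {
    "scenario": "scenario",
    "max_rate_hr": "M_P",
    "limit_strain_kpa": "L_S",
    "limit_vegf": "L_V",
    "vegf_cutoff": "V_m",
    "strain_cutoff_kpa": "S_m",
    "cell_radius_um": "R_cell",
}
_RUN_KEYS = {
    "traction_kpa": "traction",
    "tip_radius_um": "tip_radius",
    "tip_anisotropy": "tip_anisotropy",
    "t_cell_min": "t_cell_min",
    "search_radius_um": "search_radius",
    "vessel_width_um": "vessel_width",
    "initial_condition": "initial_condition",
    "cell_radius_um": "cell_radius",
    "t_end_hr": "t_end",
    "save_every_hr": "save_every",
    "dt_safety": "dt_safety",
    "store_snapshots": "store_snapshots",
}


def _section(
    raw: Dict[str, Any], name: str, keymap: Dict[str, str], errors: List[str]
) -> Dict[str, Any]:
    sec = raw.pop(name, {}) or {}
    if not isinstance(sec, dict):
        errors.append(f"section {name!r} must be a mapping")
        return {}
    out = {}
    for key, value in sec.items():
        if key not in keymap:
            errors.append(f"unknown key {name}.{key}")
        else:
            out[keymap[key]] = value
    return out


def load_config(path) -> RunConfig:
    """Parse and fully validate a run configuration file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    errors: List[str] = []
    grid_kw = _section(raw, "grid", _GRID_KEYS, errors)
    model_kw = _section(raw, "model", _MODEL_KEYS, errors)
    elastic_kw = _section(raw, "elasticity", _ELASTIC_KEYS, errors)
    vegf_kw = _section(raw, "vegf", _VEGF_KEYS, errors)
    rule_kw = _section(raw, "proliferation", _RULE_KEYS, errors)
    run_kw = _section(raw, "run", _RUN_KEYS, errors)
    for key in raw:
        errors.append(f"unknown section {key}")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    try:
        cfg = RunConfig(
            grid=GridSpec(**{"nx": 131, "ny": 101, "h": 1.0, **grid_kw}),
            params=ModelParams(
                elasticity=ElasticityParams(**elastic_kw),
                vegf=VEGFParams(**vegf_kw),
                rule=ProliferationRule(**rule_kw),
                **model_kw,
            ),
            **run_kw,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
    return cfg


def config_to_dict(cfg: RunConfig) -> Dict[str, Any]:
    """Invert :func:`load_config`: the YAML-ready mapping for a RunConfig."""

    def unmap(obj, keymap):
        d = asdict(obj) if not isinstance(obj, dict) else obj
        return {yaml_key: d[attr] for yaml_key, attr in keymap.items() if attr in d}

    rule = asdict(cfg.params.rule)
    rule["scenario"] = Scenario(cfg.params.rule.scenario).value
    run_d = {
        yaml_key: getattr(cfg, attr) for yaml_key, attr in _RUN_KEYS.items()
    }
    return {
        "grid": unmap(cfg.grid, _GRID_KEYS),
        "model": unmap(cfg.params, _MODEL_KEYS),
        "elasticity": unmap(cfg.params.elasticity, _ELASTIC_KEYS),
        "vegf": unmap(cfg.params.vegf, _VEGF_KEYS),
        "proliferation": unmap(rule, _RULE_KEYS),
        "run": run_d,
    }


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
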