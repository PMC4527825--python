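"""Snapshot and table serialization.

Field snapshots go to HDF5 with one dataset per quantity ({phi, V, w, chi_t,
strain, alpha_p}) and grid/time attributes {h_um, x0, y0, t_hr}; metrics,
events and tip tracks go to CSV with a versioned column schema.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict

import h5py
import numpy as np
import pandas as pd

from .grid import GridSpec, ScalarField

__all__ = [
    "write_snapshot",
    "read_snapshot",
    "write_trajectory",
    "METRICS_SCHEMA_VERSION",
]

METRICS_SCHEMA_VERSION = 1
_FIELD_NAMES = ("phi", "V", "w", "chi_t", "strain", "alpha_p")


def write_snapshot(path, fields: Dict[str, ScalarField], t_hr: float) -> None:
    """Write one time point; unknown field names are rejected."""
    for name in fields:
        if name not in _FIELD_NAMES:
            raise ValueError(f"unknown field {name!r}; expected {_FIELD_NAMES}")
    grids = {f.grid for f in fields.values()}
    if len(grids) != 1:
        raise ValueError("all fields in a snapshot must share a grid")
    grid = next(iter(grids))
    with h5py.File(path, "w") as fh:
        fh.attrs["h_um"] = grid.h
        fh.attrs["x0"] = grid.origin[0]
        fh.attrs["y0"] = grid.origin[1]
        fh.attrs["t_hr"] = t_hr
        for name, fld in fields.items():
            fh.create_dataset(name, data=fld.values)


def read_snapshot(path) -> tuple[Dict[str, ScalarField], float]:
    with h5py.File(path, "r") as fh:
        h = float(fh.attrs["h_um"])
        origin = (float(fh.attrs["x0"]), float(fh.attrs["y0"]))
        t_hr = float(fh.attrs["t_hr"])
        out = {}
        for name in fh:
            data = np.asarray(fh[name])
            grid = GridSpec(data.shape[0], data.shape[1], h, origin)
            out[name] = ScalarField(grid, data)
    return out, t_hr


def write_trajectory(traj, out_dir) -> None:
    """Write metrics.csv, events.csv, tip_track.csv and final-state snapshot."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics = traj.metrics.copy()
    metrics.attrs["schema_version"] = METRICS_SCHEMA_VERSION
    metrics.to_csv(out / "metrics.csv", index=False)
    pd.DataFrame(traj.events, columns=["t_hr", "kind"]).to_csv(
        out / "events.csv", index=False
    )
    traj.tip_track.to_csv(out / "tip_track.csv", index=False)
    st = traj.final
    write_snapshot(
        out / "final_state.h5",
        {"phi": st.phi, "V": st.V, "w": st.w, "chi_t": st.chi_t},
        st.t,
    )
    for t, phi in traj.snapshots:
        write_snapshot(out / f"phi_t{t:07.3f}.h5", {"phi": phi}, t)
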