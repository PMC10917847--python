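"""Time-series and result persistence."""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .network import RateTimeSeries

__all__ = ["save_timeseries", "load_timeseries", "export_rates_csv", "save_census"]

_ARRAYS = ("times", "nu_e", "nu_i", "c_ee", "c_ei", "c_ii", "W_e", "W_i")


def save_timeseries(ts: RateTimeSeries, path) -> None:
    """Write a series to HDF5, one dataset per state variable, with the
    simulation config echoed as root attributes."""
    with h5py.File(path, "w") as fh:
        for name in _ARRAYS:
            fh.create_dataset(name, data=getattr(ts, name))
        fh.attrs["dt"] = ts.dt
        for key, value in ts.config.items():
            fh.attrs[f"config_{key}"] = value


def load_timeseries(path) -> RateTimeSeries:
    with h5py.File(path, "r") as fh:
        arrays = {name: fh[name][...] for name in _ARRAYS}
        dt = float(fh.attrs["dt"])
        config = {
            key[len("config_"):]: (
                value.item() if hasattr(value, "item") else value
            )
            for key, value in fh.attrs.items()
            if key.startswith("config_")
        }
    return RateTimeSeries(dt=dt, config=config, **arrays)


def export_rates_csv(ts: RateTimeSeries, path) -> None:
    """Excitatory rates only: one column per node, time in the first."""
    header = "time_ms," + ",".join(f"node{k}" for k in range(ts.n_nodes))
    data = np.column_stack([ts.times, ts.nu_e])
    np.savetxt(path, data, delimiter=",", header=header, comments="")


def save_census(counts: np.ndarray, axes: dict, path) -> None:
    """Paroxysm census as a flat text table plus a JSON axis sidecar."""
    path = Path(path)
    np.savetxt(
        path,
        counts.reshape(counts.shape[0], -1),
        fmt="%d",
        header=f"shape={counts.shape} (S, E_L_i, E_L_e); rows=S, cols=E_L_i*E_L_e",
    )
    sidecar = path.with_suffix(path.suffix + ".axes.json")
    sidecar.write_text(
        json.dumps({k: np.asarray(v).tolist() for k, v in axes.items()}, indent=2)
    )
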