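"""Snapshot, table and configuration I/O.

Runs are archived to HDF5 (one group per snapshot, fields as datasets,
parameters and grid as root attributes), quantitative outputs go to CSV via
pandas, and run configuration round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import AHState, FieldState
from .params import GridSpec, ModelParams

__all__ = [
    "params_to_dict",
    "grid_to_dict",
    "save_run",
    "load_run",
    "save_config",
    "load_config",
    "peaks_to_frame",
]


def params_to_dict(p: ModelParams) -> dict:
    return dataclasses.asdict(p)


def grid_to_dict(g: GridSpec) -> dict:
    return dataclasses.asdict(g)


def save_run(
    path: str | Path,
    snapshots,
    p: ModelParams,
    g: GridSpec,
    **attrs,
) -> Path:
    """Write a snapshot sequence (full or reduced states) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.attrs["params"] = json.dumps(params_to_dict(p))
        fh.attrs["grid"] = json.dumps(grid_to_dict(g))
        for key, val in attrs.items():
            fh.attrs[key] = val
        for idx, snap in enumerate(snapshots):
            grp = fh.create_group(f"snap_{idx:06d}")
            grp.attrs["step"] = snap.step
            grp.attrs["t"] = snap.t
            for name in ("A", "H", "S", "Y"):
                arr = getattr(snap, name, None)
                if arr is not None:
                    grp.create_dataset(name, data=arr, compression="gzip")
    return path


def load_run(path: str | Path):
    """Read a run archive; returns (snapshots, params, grid, attrs)."""
    path = Path(path)
    snapshots = []
    with h5py.File(path, "r") as fh:
        p = ModelParams(**json.loads(fh.attrs["params"]))
        g = GridSpec(**json.loads(fh.attrs["grid"]))
        attrs = {
            k: fh.attrs[k] for k in fh.attrs if k not in ("params", "grid")
        }
        for key in sorted(fh.keys()):
            grp = fh[key]
            fields = {name: grp[name][()] for name in grp.keys()}
            step = int(grp.attrs["step"])
            t = float(grp.attrs["t"])
            if "S" in fields:
                snapshots.append(
                    FieldState(
                        fields["A"], fields["H"], fields["S"], fields["Y"],
                        t=t, step=step,
                    )
                )
            else:
                snapshots.append(
                    AHState(fields["A"], fields["H"], t=t, step=step)
                )
    return snapshots, p, g, attrs


def save_config(path: str | Path, config: dict) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config, sort_keys=False))
    return path


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def peaks_to_frame(peaks, run_id: str = "", step: int = 0) -> pd.DataFrame:
    """Flatten a PeakSet into a tidy table keyed by run id and step."""
    n = len(peaks)
    return pd.DataFrame(
        {
            "run_id": [run_id] * n,
            "step": [step] * n,
            "x": peaks.xs,
            "y": peaks.ys,
            "height": peaks.heights,
        }
    )
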