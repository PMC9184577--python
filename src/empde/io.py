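"""HDF5 / JSON / npz persistence for the pipeline artifacts."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Union

import h5py
import numpy as np

from .emergent_coords import DiffusionResult
from .pde_learning import MLP, PDEModel, PDEModelSpec
from .regrid import EmergentGrid, GriddedField
from .sampling import TransientDataset
from .simulators import TrajectoryEnsemble

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "save_dataset",
    "load_dataset",
    "save_embedding",
    "load_embedding",
    "save_gridded_field",
    "load_gridded_field",
    "save_model",
    "load_model",
    "file_sha256",
]

PathLike = Union[str, Path]


def _write_traj(group: h5py.Group, traj: TrajectoryEnsemble) -> None:
    group.create_dataset("times", data=traj.times, track_times=False)
    group.create_dataset("states", data=traj.states, track_times=False)
    group.attrs["meta"] = json.dumps(traj.meta, default=str)


def _read_traj(group: h5py.Group) -> TrajectoryEnsemble:
    return TrajectoryEnsemble(
        times=group["times"][:],
        states=group["states"][:],
        meta=json.loads(group.attrs.get("meta", "{}")),
    )


def save_trajectory(path: PathLike, traj: TrajectoryEnsemble) -> None:
    with h5py.File(path, "w") as f:
        _write_traj(f, traj)


def load_trajectory(path: PathLike) -> TrajectoryEnsemble:
    with h5py.File(path, "r") as f:
        return _read_traj(f)


def save_dataset(path: PathLike, ds: TransientDataset) -> None:
    """Datasets as /train/i and /val/i groups with per-group gamma attrs."""
    with h5py.File(path, "w") as f:
        counters = {"train": 0, "val": 0}
        for i, (traj, tag) in enumerate(zip(ds.trajectories, ds.split)):
            g = f.create_group(f"{tag}/{counters[tag]}")
            counters[tag] += 1
            _write_traj(g, traj)
            if ds.gamma_values is not None:
                g.attrs["gamma"] = ds.gamma_values[i]
        f.attrs["meta"] = json.dumps(ds.meta, default=str)


def load_dataset(path: PathLike) -> TransientDataset:
    trajectories, split, gammas = [], [], []
    has_gamma = False
    with h5py.File(path, "r") as f:
        for tag in ("train", "val"):
            if tag not in f:
                continue
            for key in sorted(f[tag], key=int):
                g = f[tag][key]
                trajectories.append(_read_traj(g))
                split.append(tag)
                if "gamma" in g.attrs:
                    has_gamma = True
                    gammas.append(float(g.attrs["gamma"]))
                else:
                    gammas.append(np.nan)
        meta = json.loads(f.attrs.get("meta", "{}"))
    return TransientDataset(
        trajectories, split, gamma_values=gammas if has_gamma else None, meta=meta
    )


def save_embedding(path: PathLike, dr: DiffusionResult) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("eigenvalues", data=dr.eigenvalues, track_times=False)
        f.create_dataset("modes", data=dr.eigenvectors, track_times=False)
        f.attrs["kernel_scale"] = dr.kernel_scale
        if dr.selected is not None:
            f.create_dataset("selected", data=np.asarray(dr.selected), track_times=False)
        if dr.scaled_modes is not None:
            f.create_dataset("scaled_modes", data=dr.scaled_modes, track_times=False)
        if dr.scaling is not None:
            f.create_dataset("scaling", data=np.asarray(dr.scaling), track_times=False)


def load_embedding(path: PathLike) -> DiffusionResult:
    with h5py.File(path, "r") as f:
        dr = DiffusionResult(
            kernel_scale=float(f.attrs["kernel_scale"]),
            eigenvalues=f["eigenvalues"][:],
            eigenvectors=f["modes"][:],
        )
        if "selected" in f:
            dr.selected = [int(i) for i in f["selected"][:]]
        if "scaled_modes" in f:
            dr.scaled_modes = f["scaled_modes"][:]
        if "scaling" in f:
            dr.scaling = [tuple(row) for row in f["scaling"][:]]
    return dr


def save_gridded_field(path: PathLike, gf: GriddedField) -> None:
    with h5py.File(path, "w") as f:
        for i, ax in enumerate(gf.grid.axes):
            f.create_dataset(f"grid/axis{i}", data=ax, track_times=False)
        f.attrs["periodic"] = np.asarray(gf.grid.periodic)
        f.create_dataset("values", data=gf.values, track_times=False)
        if gf.times is not None:
            f.create_dataset("times", data=gf.times, track_times=False)
        if gf.dWdt is not None:
            f.create_dataset("dwdt", data=gf.dWdt, track_times=False)
        f.attrs["meta"] = json.dumps(gf.meta, default=str)


def load_gridded_field(path: PathLike) -> GriddedField:
    with h5py.File(path, "r") as f:
        axes = [f[f"grid/axis{i}"][:] for i in range(len(f["grid"]))]
        grid = EmergentGrid(axes=axes, periodic=tuple(bool(p) for p in f.attrs["periodic"]))
        return GriddedField(
            grid,
            f["values"][:],
            times=f["times"][:] if "times" in f else None,
            dWdt=f["dwdt"][:] if "dwdt" in f else None,
            meta=json.loads(f.attrs.get("meta", "{}")),
        )


def save_model(path: PathLike, model: PDEModel) -> None:
    """Single-file archive: architecture spec as JSON plus the weight block.

    Stored as HDF5 with object timestamps disabled, so identical models
    serialize to bytewise-identical files.
    """
    spec_json = json.dumps(model.spec.__dict__, default=str)
    state = model.net.state_dict()
    with h5py.File(path, "w") as f:
        f.attrs["spec"] = spec_json
        f.attrs["activation"] = str(np.asarray(state.pop("activation")))
        for key, val in state.items():
            f.create_dataset(key, data=np.asarray(val), track_times=False)


def load_model(path: PathLike) -> PDEModel:
    with h5py.File(path, "r") as f:
        spec_dict = json.loads(f.attrs["spec"])
        if spec_dict.get("spacing") is not None:
            spec_dict["spacing"] = tuple(float(s) for s in spec_dict["spacing"])
        spec = PDEModelSpec(**spec_dict)
        state = {key: f[key][:] for key in f}
        state["activation"] = np.array(f.attrs["activation"])
        net = MLP.from_state_dict(state)
    return PDEModel(spec=spec, net=net)


def file_sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
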