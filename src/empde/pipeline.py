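"""Configuration-driven orchestration of the emergent-PDE workflow.

A single experiment runs simulate -> sample -> embed -> regrid -> train ->
rollout -> analyze, each stage reading the previous stage's artifact from the
output directory and writing its own (HDF5/CSV/JSON) plus a manifest of
content hashes, so that re-running a stage with the same config and seed
reproduces identical artifacts.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import io as eio
from .emergent_coords import (
    circular_coordinate,
    embed_features,
    ensemble_feature_matrix,
)
from .pde_learning import PDEModelSpec, TrainConfig, assemble_features, train_pde_model
from .regrid import EmergentGrid, GriddedField, resample_line
from .rollout import RolloutConfig, fit_svd_filter, integrate_learned_pde
from .sampling import SamplingPlan, generate_transient_dataset
from .simulators import (
    CGLEParams,
    HHNetworkParams,
    SLEnsembleParams,
    simulate_cgle,
    simulate_hh_network,
    simulate_sl_ensemble,
)

__all__ = ["ExperimentConfig", "load_config", "run_pipeline", "ALL_STAGES",
           "DEFAULT_CONFIGS"]

log = logging.getLogger("empde")

ALL_STAGES = ("simulate", "sample", "embed", "regrid", "train", "rollout", "analyze")

#: canonical per-experiment defaults (the study conditions); any entry can be
#: overridden from a user YAML file.
DEFAULT_CONFIGS: dict = {
    "cgle_chaotic": {
        "system": "cgle_chaotic",
        "params": {"c1": 0.0, "c2": -3.0, "L": 80.0, "n_mesh": 256,
                   "boundary": "periodic", "dt_sample": 0.02},
        "plan": {"n_lc": 20, "n_test": 2, "perturb_mode": "scale_factors",
                 "horizon": 20.0, "dt": 0.02},
        "sampling_options": {"t_burn": 1000.0, "noise_sigma": 0.1},
        "embed": {"eps": 100.0, "n_modes": 12,
                  "selection": "local_linear_regression",
                  "selection_params": {"threshold": 0.5, "max_modes": 2}},
        "grid": {"n": 256, "periodic": True},
        "model": {"n_derivs": 2, "stencil_length": 5, "hidden_layers": 4,
                  "width": 96, "activation": "swish"},
        "train": {"lr": 2e-3, "batch": 128, "epochs": 400, "patience": 10},
        "rollout": {"scheme": "rk45", "dt": 0.02, "boundary": "periodic",
                    "n_keep": None, "horizon": 4.0},
    },
    "cgle_noflux": {
        "system": "cgle_noflux",
        "params": {"c1": 1.0, "c2": 2.0, "L": 200.0, "n_mesh": 256,
                   "boundary": "no_flux", "dt_sample": 1e-3},
        "plan": {"n_lc": 20, "n_test": 1, "perturb_mode": "scale_factors",
                 "factors": [0.9, 1.1], "horizon": 20.0, "dt": 1e-3,
                 "d_tau": 100.0, "t_min": 2000.0},
        "sampling_options": {"n_keep_agents": 128},
        "embed": {"eps": "median", "n_modes": 12,
                  "selection": "local_linear_regression",
                  "selection_params": {"threshold": 0.5, "max_modes": 1}},
        "grid": {"n": 128, "periodic": False},
        "model": {"n_derivs": 3, "stencil_length": 9, "hidden_layers": 4,
                  "width": 96, "activation": "tanh"},
        "train": {"lr": 1e-3, "batch": 1024, "epochs": 60, "patience": 7},
        "rollout": {"scheme": "forward_euler", "dt": 1e-3, "boundary": "corridor",
                    "corridor_width": 4, "n_keep": 2, "horizon": 2.0},
    },
    "sl_fixed_gamma": {
        "system": "sl",
        "params": {"K": 1.2, "gamma": 1.7, "omega0": 0.2, "n_osc": 512},
        "plan": {"n_lc": 20, "n_test": 5, "perturb_mode": "floquet_direction",
                 "eps_perturb": 0.1, "horizon": 200.0, "dt": 0.05},
        "sampling_options": {"settle_time": 400.0, "monodromy_steps": 1024},
        "embed": {"eps": 20.0, "n_modes": 12,
                  "selection": "local_linear_regression",
                  "selection_params": {"threshold": 0.5, "max_modes": 1}},
        "grid": {"n": 128, "periodic": False},
        "model": {"n_derivs": 3, "stencil_length": 9, "hidden_layers": 4,
                  "width": 96, "activation": "tanh"},
        "train": {"lr": 1e-3, "batch": 1024, "epochs": 60, "patience": 7},
        "rollout": {"scheme": "forward_euler", "dt": 0.05, "boundary": "corridor",
                    "corridor_width": 4, "n_keep": 3, "horizon": 20.0},
    },
    "sl_gamma_sweep": {
        "system": "sl_gamma_sweep",
        "params": {"K": 1.2, "gamma": 1.7, "omega0": 0.2, "n_osc": 512},
        "gamma_values": [1.7, 1.72, 1.74, 1.76, 1.78, 1.8],
        "plan": {"n_lc": 20, "n_test": 5, "perturb_mode": "floquet_direction",
                 "eps_perturb": 0.1, "horizon": 200.0, "dt": 0.05},
        "sampling_options": {"settle_time": 400.0, "monodromy_steps": 1024},
        "embed": {"eps": 10.0, "n_modes": 12,
                  "selection": "local_linear_regression",
                  "selection_params": {"threshold": 0.5, "max_modes": 1}},
        "grid": {"n": 128, "periodic": False},
        "model": {"n_derivs": 3, "stencil_length": 9, "hidden_layers": 4,
                  "width": 96, "activation": "tanh", "param_input": True},
        "train": {"lr": 1e-3, "batch": 1024, "epochs": 60, "patience": 7},
        "rollout": {"scheme": "forward_euler", "dt": 0.05, "boundary": "corridor",
                    "corridor_width": 4, "n_keep": 3, "horizon": 20.0},
    },
    "hh_prebotzinger": {
        "system": "hh",
        "params": {"n_neurons": 1024},
        "plan": {"n_lc": 3, "n_test": 1, "perturb_mode": "scale_factors",
                 "factors": [0.9, 1.1], "horizon": 20.0, "dt": 2e-3},
        "sampling_options": {},
        "embed": {"eps": 4000.0, "n_modes": 12,
                  "selection": "local_linear_regression",
                  "selection_params": {"threshold": 0.5, "max_modes": 2}},
        "grid": {"n": 64, "fraction": 0.7},
        "model": {"n_derivs": 3, "stencil_length": 5, "hidden_layers": 3,
                  "width": 64, "activation": "tanh"},
        "train": {"lr": 2e-3, "batch": 128, "epochs": 400, "patience": 10},
        "rollout": {"scheme": "forward_euler", "dt": 2e-3, "boundary": "corridor",
                    "corridor_width": 4, "n_keep": 10, "horizon": 2.0},
    },
}


class ExperimentConfig(dict):
    """A validated experiment configuration (a dict with known blocks)."""

    REQUIRED = ("system", "params", "plan", "embed", "grid", "model", "train",
                "rollout")

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        experiment = raw.get("experiment", "custom")
        if experiment != "custom":
            if experiment not in DEFAULT_CONFIGS:
                raise ValueError(f"unknown experiment {experiment!r}")
            merged = copy.deepcopy(DEFAULT_CONFIGS[experiment])
            for key, val in raw.items():
                if isinstance(val, dict) and isinstance(merged.get(key), dict):
                    merged[key].update(val)
                else:
                    merged[key] = val
        else:
            merged = copy.deepcopy(raw)
        merged.setdefault("experiment", experiment)
        merged.setdefault("seed", 0)
        cfg = cls(merged)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        missing = [k for k in self.REQUIRED if k not in self]
        if missing:
            raise ValueError(f"config is missing required blocks: {missing}")
        if self["system"] not in (
            "cgle_chaotic", "cgle_noflux", "sl", "sl_gamma_sweep", "hh"
        ):
            raise ValueError(f"unknown system {self['system']!r}")


def load_config(path) -> ExperimentConfig:
    with open(path) as f:
        raw = yaml.safe_load(f)
    return ExperimentConfig.from_dict(raw)


def _build_params(cfg: ExperimentConfig):
    system = cfg["system"]
    p = cfg["params"]
    if system in ("cgle_chaotic", "cgle_noflux"):
        return CGLEParams(**{**p, "dt_sample": cfg["plan"]["dt"]})
    if system in ("sl", "sl_gamma_sweep"):
        return SLEnsembleParams(**p)
    if system == "hh":
        return HHNetworkParams.random(seed=cfg["seed"], **p)
    raise ValueError(system)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg, outdir: Path) -> None:
    params = _build_params(cfg)
    system = cfg["system"]
    seed = cfg["seed"]
    if system == "cgle_chaotic":
        traj = simulate_cgle(params, seed=seed,
                             t_burn=cfg["sampling_options"].get("t_burn", 1000.0),
                             t_sample=cfg["plan"]["horizon"])
    elif system == "cgle_noflux":
        x = params.x
        ic = ((1.0 + np.cos(np.pi * x / params.L)) / 2.0).astype(complex)
        traj = simulate_cgle(params, ic=ic, t_burn=cfg["plan"].get("t_min", 2000.0),
                             t_sample=cfg["plan"]["horizon"])
    elif system in ("sl", "sl_gamma_sweep"):
        traj = simulate_sl_ensemble(
            params, seed=seed,
            t_span=(0.0, cfg["sampling_options"].get("settle_time", 400.0)),
            dt_sample=cfg["plan"]["dt"])
    else:
        traj = simulate_hh_network(params)
    eio.save_trajectory(outdir / "simulate.h5", traj)


def _stage_sample(cfg, outdir: Path) -> None:
    plan_kwargs = dict(cfg["plan"])
    if "factors" in plan_kwargs:
        plan_kwargs["factors"] = tuple(plan_kwargs["factors"])
    plan = SamplingPlan(**plan_kwargs)
    params = _build_params(cfg)
    ds = generate_transient_dataset(
        cfg["system"], plan, seed=cfg["seed"], params=params,
        gamma_values=cfg.get("gamma_values"), **cfg.get("sampling_options", {}),
    )
    eio.save_dataset(outdir / "dataset.h5", ds)


def _stage_embed(cfg, outdir: Path) -> None:
    ds = eio.load_dataset(outdir / "dataset.h5")
    feats = ensemble_feature_matrix(ds.subset("train"))
    e = cfg["embed"]
    dr = embed_features(feats, eps=e.get("eps", "median"),
                        n_modes=e.get("n_modes", 12),
                        selection=e.get("selection", "local_linear_regression"),
                        selection_params=e.get("selection_params"))
    eio.save_embedding(outdir / "embedding.h5", dr)


def _emergent_coordinate(cfg, dr):
    """Per-agent 1D coordinate (plus periodic flag) from the embedding."""
    if len(dr.selected) >= 2 and cfg["grid"].get("periodic", False):
        angles = circular_coordinate(dr.scaled_modes[:, 0], dr.scaled_modes[:, 1])
        return angles.values, True
    return dr.scaled_modes[:, 0], False


def _stage_regrid(cfg, outdir: Path) -> None:
    ds = eio.load_dataset(outdir / "dataset.h5")
    dr = eio.load_embedding(outdir / "embedding.h5")
    coord, periodic = _emergent_coordinate(cfg, dr)
    n = cfg["grid"]["n"]
    if periodic:
        grid = EmergentGrid.line(-np.pi, np.pi, n, periodic=True)
    else:
        grid = EmergentGrid.line(-1.0, 1.0, n, periodic=False)
    method = cfg["grid"].get("method", "cubic")
    for tag in ("train", "val"):
        stack, gammas = [], []
        for i, traj in enumerate(ds.subset(tag)):
            gf = resample_line(coord, traj.states, grid, periodic=periodic,
                               method=method if not periodic else "cubic")
            stack.append(gf.values.astype(np.float32))
        if not stack:
            continue
        arr = np.stack(stack)  # (trajs, T, n, ch)
        out = GriddedField(grid, arr.reshape(-1, *arr.shape[2:]),
                           meta={"n_traj": len(stack), "dt": ds.trajectories[0].dt,
                                 "tag": tag, "shape": list(arr.shape)})
        eio.save_gridded_field(outdir / f"grid_{tag}.h5", out)
    if ds.gamma_values is not None:
        gammas = {"train": [], "val": []}
        for g, tag in zip(ds.gamma_values, ds.split):
            gammas[tag].append(g)
        (outdir / "gammas.json").write_text(json.dumps(gammas))


def _load_gridded_stack(cfg, outdir: Path, tag: str):
    gf = eio.load_gridded_field(outdir / f"grid_{tag}.h5")
    shape = gf.meta["shape"]
    arr = gf.values.reshape(shape)
    return gf.grid, arr, float(gf.meta["dt"])


def _assemble(cfg, grid, arr, dt, gammas=None):
    spec = _model_spec(cfg, grid)
    Xs, Ys = [], []
    for i in range(arr.shape[0]):
        fields = arr[i].astype(float)
        targets = np.diff(fields, axis=0) / dt
        g = None if gammas is None else gammas[i]
        X, Y = assemble_features(fields, targets, spec, gamma=g)
        Xs.append(X)
        Ys.append(Y)
    return spec, np.concatenate(Xs), np.concatenate(Ys)


def _model_spec(cfg, grid) -> PDEModelSpec:
    m = cfg["model"]
    periodic = grid.periodic[0]
    return PDEModelSpec(
        n_derivs=m["n_derivs"],
        channels=2,
        hidden_layers=m.get("hidden_layers", 4),
        width=m.get("width", 96),
        activation=m.get("activation", "tanh"),
        param_input=m.get("param_input", False),
        stencil_length=m.get("stencil_length", 5),
        boundary="periodic" if periodic else "interior_only",
        n_space=grid.dims,
        spacing=grid.spacing,
    )


def _stage_train(cfg, outdir: Path) -> None:
    grid, arr_tr, dt = _load_gridded_stack(cfg, outdir, "train")
    gammas = None
    gpath = outdir / "gammas.json"
    if gpath.exists():
        gammas = json.loads(gpath.read_text())
    spec, X, Y = _assemble(cfg, grid, arr_tr, dt,
                           None if gammas is None else gammas["train"])
    try:
        grid_v, arr_v, _ = _load_gridded_stack(cfg, outdir, "val")
        _, Xv, Yv = _assemble(cfg, grid_v, arr_v, dt,
                              None if gammas is None else gammas["val"])
    except FileNotFoundError:
        cut = max(1, X.shape[0] // 10)
        Xv, Yv = X[-cut:], Y[-cut:]
        X, Y = X[:-cut], Y[:-cut]
    t = cfg["train"]
    tc = TrainConfig(lr=t.get("lr", 1e-3), batch=t.get("batch", 128),
                     epochs=t.get("epochs", 60), patience=t.get("patience", 10),
                     seed=cfg["seed"])
    model = train_pde_model(spec, X, Y, Xv, Yv, tc)
    eio.save_model(outdir / "model.h5", model)
    hist = model.history
    lines = ["epoch,train_loss,val_loss,lr"]
    for i in range(len(hist["train_loss"])):
        lines.append(f"{i},{hist['train_loss'][i]},{hist['val_loss'][i]},{hist['lr'][i]}")
    (outdir / "training_curve.csv").write_text("\n".join(lines) + "\n")


def _stage_rollout(cfg, outdir: Path) -> None:
    model = eio.load_model(outdir / "model.h5")
    tag = "val" if (outdir / "grid_val.h5").exists() else "train"
    grid, arr, dt = _load_gridded_stack(cfg, outdir, tag)
    truth = arr[0].astype(float)
    r = cfg["rollout"]
    n_keep = r.get("n_keep")
    filt = None
    if n_keep:
        grid_tr, arr_tr, _ = _load_gridded_stack(cfg, outdir, "train")
        snaps = arr_tr.reshape(-1, arr_tr.shape[-2] * arr_tr.shape[-1]).astype(float)
        filt = fit_svd_filter(snaps, n_keep)
    horizon = min(r.get("horizon", 1.0), (truth.shape[0] - 1) * dt)
    gamma = None
    gpath = outdir / "gammas.json"
    if model.spec.param_input and gpath.exists():
        gamma = json.loads(gpath.read_text())[tag][0]
    rcfg = RolloutConfig(dt=dt, scheme=r.get("scheme", "forward_euler"),
                         boundary=r.get("boundary", "corridor"),
                         corridor_width=r.get("corridor_width", 4), filter=filt)
    n_steps = int(round(horizon / dt))
    gf = integrate_learned_pde(model, truth[0], rcfg, horizon,
                               bc_source=truth[: n_steps + 1], gamma=gamma,
                               grid=grid)
    eio.save_gridded_field(outdir / "rollout.h5", gf)


def _stage_analyze(cfg, outdir: Path) -> None:
    gf = eio.load_gridded_field(outdir / "rollout.h5")
    tag = "val" if (outdir / "grid_val.h5").exists() else "train"
    _, arr, dt = _load_gridded_stack(cfg, outdir, tag)
    truth = arr[0][: gf.values.shape[0]].astype(float)
    num = np.linalg.norm(gf.values - truth)
    den = np.linalg.norm(truth)
    report = {
        "rollout_relative_l2": float(num / den),
        "rollout_horizon": float(gf.values.shape[0] * dt),
        "tag": tag,
    }
    (outdir / "analysis.json").write_text(json.dumps(report, indent=2))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "sample": _stage_sample,
    "embed": _stage_embed,
    "regrid": _stage_regrid,
    "train": _stage_train,
    "rollout": _stage_rollout,
    "analyze": _stage_analyze,
}


def run_pipeline(
    config: dict,
    stages: Optional[Sequence[str]] = None,
    outdir="runs/experiment",
) -> Path:
    """Execute the requested stages in order; returns the artifact directory.

    Each stage writes its artifact into ``outdir``; a manifest maps artifact
    names to SHA-256 hashes together with the config and seed, establishing
    provenance. Missing upstream artifacts raise ``FileNotFoundError`` naming
    the stage to run first.
    """
    cfg = config if isinstance(config, ExperimentConfig) else ExperimentConfig.from_dict(config)
    stages = list(stages or ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        for stage in ALL_STAGES:
            if stage not in stages:
                continue
            t0 = time.time()
            log.info("stage %s starting", stage)
            _STAGE_FUNCS[stage](cfg, outdir)
            log.info("stage %s done in %.1fs", stage, time.time() - t0)
    finally:
        log.removeHandler(handler)
        handler.close()

    manifest = {"config": dict(cfg), "seed": cfg["seed"], "artifacts": {}}
    for f in sorted(outdir.iterdir()):
        if f.name in ("manifest.json", "run.log") or f.is_dir():
            continue
        manifest["artifacts"][f.name] = eio.file_sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
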