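"""Config-driven experiment pipelines: simulate -> train -> analyze.

An :class:`ExperimentConfig` names a task (cards / arena / arm), a scale
preset, a training mode and the three seeds; :func:`run_experiment`
executes the stages into an output directory with a JSON manifest, skipping
any stage already completed for the same config hash (idempotent, resumable
runs).  :func:`compare_conditions` runs paired predictive / non-predictive
ensembles and averages their metric timelines.

Scale presets
-------------
"full"     full-scale conditions (64x64 arena, 500 units, 10^6-step epochs);
           hours of compute, intended for manual launches only.
"reduced"  16x16 arena / 100 units / 10^5 steps: the desk-scale conditions
           used throughout the test battery's trend checks.
"fixture"  minutes-scale smoke configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from predrep.envs import arena as arena_env
from predrep.envs import arm as arm_env
from predrep.envs import cards as cards_env
from predrep.metrics.invariance import translation_invariance_score
from predrep.metrics.timeline import TimelineConfig, build_metric_timeline
from predrep.metrics.transfer import signal_transfer
from predrep.models import FeedforwardPredictor, RecurrentPredictor
from predrep.trajectory import Trajectory

__all__ = [
    "ExperimentConfig",
    "PRESETS",
    "run_experiment",
    "compare_conditions",
    "card_probe",
    "card_latent_transfer",
]

PRESETS: dict[str, dict[str, dict]] = {
    "cards": {
        # the lattice network trains with plain SGD: its implicit bias is
        # what yields the translation-invariant first layer
        "full": dict(grid_shape=(5, 5), n_steps=1_000_000, n_hidden=100, max_epochs=60,
                      train=dict(optimizer="sgd", learning_rate=20.0, batch_size=256,
                                 init_std=0.005)),
        "reduced": dict(grid_shape=(5, 5), n_steps=200_000, n_hidden=100, max_epochs=25,
                        train=dict(optimizer="sgd", learning_rate=20.0, batch_size=256,
                                   init_std=0.005)),
        "fixture": dict(grid_shape=(4, 4), n_steps=10_000, n_hidden=40, max_epochs=10,
                        train=dict(optimizer="sgd", learning_rate=20.0, batch_size=256,
                                   init_std=0.005)),
    },
    "arena": {
        "full": dict(size=64, n_steps=1_000_000, n_units=500, max_epochs=200,
                      probe_steps=100_000, train=dict()),
        "reduced": dict(size=16, n_steps=100_000, n_units=100, max_epochs=300,
                        probe_steps=20_000, train=dict(batch_size=16)),
        "fixture": dict(size=8, n_steps=5_000, n_units=32, max_epochs=4,
                        probe_steps=2_000, train=dict()),
    },
    "arm": {
        "full": dict(n_steps=1_000_000, n_units=500, max_epochs=200,
                      probe_steps=100_000, train=dict()),
        "reduced": dict(n_steps=100_000, n_units=100, max_epochs=60,
                        probe_steps=20_000, train=dict()),
        "fixture": dict(n_steps=5_000, n_units=32, max_epochs=4,
                        probe_steps=2_000, train=dict()),
    },
}


@dataclass
class ExperimentConfig:
    task: str = "arena"
    scale: str = "reduced"
    mode: str = "predictive"
    include_actions: bool = True
    env_seed: int = 0
    train_seed: int = 1
    metric_seed: int = 2
    timeline_stride: int = 25  # evaluate every k-th checkpoint
    env_overrides: dict = field(default_factory=dict)
    train_overrides: dict = field(default_factory=dict)

    def expand(self) -> dict:
        """Fully explicit parameter set for this config."""
        if self.task not in PRESETS or self.scale not in PRESETS[self.task]:
            raise ValueError(f"unknown task/scale: {self.task}/{self.scale}")
        params = dict(PRESETS[self.task][self.scale])
        params.update(self.env_overrides)
        return params

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# -- card-task probing -----------------------------------------------------


def card_probe(world: cards_env.CardWorld) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (observation-class, action) input conditions of a card world.

    Returns (obs encodings, one-hot actions, next-state coordinates) with
    one row per condition (n_states * n_actions, e.g. 125 on a 5x5 world);
    coordinates are NaN for boundary conditions whose move is invalid.
    """
    obs_rows, act_rows, coords = [], [], []
    for s in world.all_states():
        o = cards_env.encode_card_observation(world, s)
        for a in range(world.n_actions):
            onehot = np.zeros(world.n_actions)
            onehot[a] = 1.0
            obs_rows.append(o)
            act_rows.append(onehot)
            try:
                coords.append(np.asarray(cards_env.lattice_step(s, a, world.grid_shape), float))
            except cards_env.InvalidMoveError:
                coords.append(np.full(len(world.grid_shape), np.nan))
    return np.array(obs_rows), np.array(act_rows), np.array(coords)


def card_latent_transfer(
    representation: np.ndarray, next_coords: np.ndarray, n_pcs: int = 2
) -> float:
    """Mean CC between condition-representation PCs and predicted-state
    lattice coordinates, over the valid (in-grid) conditions."""
    valid = np.all(np.isfinite(next_coords), axis=1)
    return signal_transfer(representation[valid], next_coords[valid], n_pcs)


def card_metric_timeline(
    net: FeedforwardPredictor, world: cards_env.CardWorld
) -> pd.DataFrame:
    """Per-checkpoint latent transfer and translation-invariance score."""
    obs, act, coords = card_probe(world)
    rows = []
    for epoch, w in net.checkpoints_:
        rep = net.representations(obs, act, weights=w)
        rows.append(
            {
                "epoch": epoch,
                "latent_transfer": card_latent_transfer(rep, coords),
                "invariance_score": translation_invariance_score(w["W_o"], world),
            }
        )
    return pd.DataFrame(rows)


# -- stage runners ---------------------------------------------------------


def _simulate(config: ExperimentConfig, params: dict) -> tuple[Trajectory, Trajectory | None]:
    if config.task == "cards":
        world = cards_env.build_card_world(
            grid_shape=tuple(params["grid_shape"]), seed=config.env_seed
        )
        traj = cards_env.generate_card_trajectory(world, params["n_steps"], seed=config.env_seed)
        return traj, None
    if config.task == "arena":
        ar = arena_env.build_arena(size=params["size"], seed=config.env_seed)
        walk = arena_env.WalkConfig()
        traj = arena_env.generate_spatial_trajectory(ar, walk, params["n_steps"], seed=config.env_seed)
        probe = arena_env.generate_spatial_trajectory(
            ar, walk, params["probe_steps"], seed=config.env_seed + 10_000
        )
        return traj, probe
    if config.task == "arm":
        p = arm_env.ArmParams()
        traj = arm_env.generate_arm_trajectory(p, params["n_steps"], seed=config.env_seed)
        probe = arm_env.generate_arm_trajectory(
            p, params["probe_steps"], seed=config.env_seed + 10_000
        )
        return traj, probe
    raise ValueError(f"unknown task {config.task!r}")


def _train(config: ExperimentConfig, params: dict, traj: Trajectory):
    train_kwargs = dict(params.get("train", {}))
    train_kwargs.update(config.train_overrides)
    if config.task == "cards":
        net = FeedforwardPredictor(
            n_hidden=params["n_hidden"],
            max_epochs=params["max_epochs"],
            include_actions=config.include_actions,
            seed=config.train_seed,
            **train_kwargs,
        )
    else:
        net = RecurrentPredictor(
            n_units=params["n_units"],
            mode=config.mode,
            include_actions=config.include_actions,
            max_epochs=params["max_epochs"],
            seed=config.train_seed,
            **train_kwargs,
        )
    return net.fit(traj)


def _timeline_config(config: ExperimentConfig) -> TimelineConfig:
    circular = (2,) if config.task == "arena" else ()
    return TimelineConfig(
        latent_columns=(0, 1), circular_columns=circular, seed=config.metric_seed
    )


def run_experiment(config: ExperimentConfig, outdir: str | Path) -> dict:
    """Execute simulate -> train -> metrics into `outdir`; resumable.

    Returns the run manifest.  A stage already marked complete for the same
    config hash is loaded from disk instead of re-executed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    h = config.config_hash()
    manifest = {"config": dataclasses.asdict(config), "hash": h, "stages": {}, "files": {}}
    if manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("hash") == h:
            manifest = prev

    params = config.expand()

    def done(stage: str) -> bool:
        return manifest["stages"].get(stage) == "done"

    def mark(stage: str, files: dict) -> None:
        manifest["stages"][stage] = "done"
        manifest["files"].update(files)
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    # stage 1: simulate
    if done("simulate"):
        traj = Trajectory.load(outdir / "traj_train")
        probe = Trajectory.load(outdir / "traj_probe") if (outdir / "traj_probe").exists() else None
    else:
        traj, probe = _simulate(config, params)
        traj.save(outdir / "traj_train")
        files = {"traj_train": "traj_train"}
        if probe is not None:
            probe.save(outdir / "traj_probe")
            files["traj_probe"] = "traj_probe"
        mark("simulate", files)

    # stage 2: train
    ckpt_path = outdir / "checkpoints.npz"
    if done("train") and ckpt_path.exists():
        net = _load_net(config, params, ckpt_path, traj)
    else:
        try:
            net = _train(config, params, traj)
        except Exception as err:
            manifest["stages"]["train"] = f"failed: {err}"
            manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
            raise
        _save_net(net, ckpt_path)
        pd.DataFrame(
            net.loss_history_, columns=["epoch", "train_loss", "val_loss", "learning_rate"]
        ).to_csv(outdir / "loss_history.csv", index=False)
        mark("train", {"checkpoints": "checkpoints.npz", "loss_history": "loss_history.csv"})

    # stage 3: metrics
    if not done("metrics"):
        if config.task == "cards":
            world = cards_env.build_card_world(
                grid_shape=tuple(params["grid_shape"]), seed=config.env_seed
            )
            df = card_metric_timeline(net, world)
        else:
            ckpts = net.checkpoints_[:: config.timeline_stride]
            if ckpts[-1][0] != net.checkpoints_[-1][0]:
                ckpts.append(net.checkpoints_[-1])
            tl = build_metric_timeline(net, ckpts, probe, _timeline_config(config))
            df = tl.records
        df.to_csv(outdir / "timeline.csv", index=False)
        mark("metrics", {"timeline": "timeline.csv"})

    return manifest


def _save_net(net, path: Path) -> None:
    arrays = {}
    for epoch, w in net.checkpoints_:
        for k, v in w.items():
            arrays[f"e{epoch}:{k}"] = v
    for k, v in net.weights_.items():
        arrays[f"final:{k}"] = v
    meta = {"params": net.get_params()}
    if hasattr(net, "obs_center_"):
        meta["obs_center"] = net.obs_center_
        meta["obs_gain"] = net.obs_gain_
    arrays["__meta__"] = np.frombuffer(json.dumps(meta, default=str).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def _load_net(config: ExperimentConfig, params: dict, path: Path, traj: Trajectory):
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        weights = {}
        ckpts: dict[int, dict] = {}
        for key in data.files:
            if key == "__meta__":
                continue
            tag, name = key.split(":", 1)
            if tag == "final":
                weights[name] = data[key]
            else:
                ckpts.setdefault(int(tag[1:]), {})[name] = data[key]
    if config.task == "cards":
        net = FeedforwardPredictor(**meta["params"])
        net.n_obs_dims_ = weights["W_o"].shape[1]
        net.n_action_dims_ = weights["W_a"].shape[1]
    else:
        net = RecurrentPredictor(**meta["params"])
        net.obs_center_ = meta["obs_center"]
        net.obs_gain_ = meta["obs_gain"]
        net.n_obs_dims_ = weights["W_o"].shape[1]
        net.n_action_dims_ = weights["W_a"].shape[1]
    net.weights_ = weights
    net.checkpoints_ = [(e, ckpts[e]) for e in sorted(ckpts)]
    net.loss_history_ = []
    return net


def compare_conditions(
    config_predictive: ExperimentConfig,
    config_nonpredictive: ExperimentConfig,
    n_replicates: int = 5,
    outdir: str | Path = "runs/compare",
) -> pd.DataFrame:
    """Replicate-averaged metric timelines for paired conditions.

    The two configs must differ only in `mode`; replicate i of both
    conditions shares seeds (paired design).  Returns a long-format table
    (condition, replicate, epoch, metric columns); failed replicates are
    excluded with a console note.
    """
    a, b = dataclasses.asdict(config_predictive), dataclasses.asdict(config_nonpredictive)
    a.pop("mode"), b.pop("mode")
    if a != b:
        raise ValueError("configs must differ only in mode")
    outdir = Path(outdir)
    frames = []
    for rep in range(n_replicates):
        for cfg in (config_predictive, config_nonpredictive):
            c = dataclasses.replace(
                cfg,
                env_seed=cfg.env_seed + 100 * rep,
                train_seed=cfg.train_seed + 100 * rep,
            )
            rundir = outdir / f"{c.mode}_{rep}"
            try:
                run_experiment(c, rundir)
            except Exception as err:
                print(f"replicate {rep} ({c.mode}) failed: {err}")
                continue
            df = pd.read_csv(rundir / "timeline.csv")
            df["condition"] = c.mode
            df["replicate"] = rep
            frames.append(df)
    if not frames:
        raise RuntimeError("all replicates failed")
    return pd.concat(frames, ignore_index=True)
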