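"""Shared trajectory container for all simulated environments.

A :class:`Trajectory` holds three aligned sequences: the latent state of the
generative process (never shown to a network), the action code emitted at
each step, and the observation vector the agent receives.  All three have
the same length ``T``.  Networks are trained purely on ``(observations,
actions)``; the latents are retained for the downstream manifold analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Aligned (latent state, action, observation) sequences of length T.

    Parameters
    ----------
    states : ndarray, shape (T,) or (T, k)
        Integer or float encoding of the latent state per step (lattice
        coordinates, (x, y, theta), or joint angles).
    actions : ndarray, shape (T,)
        Integer action codes.
    observations : ndarray, shape (T, D)
        Observation vector per step.
    n_action_classes : int
        Size of the one-hot action alphabet.
    latents : ndarray, shape (T, m), optional
        Continuous latent trace used by the metrics layer.  Defaults to
        ``states`` cast to float.
    meta : dict
        Provenance: seed, environment parameters, encoding scheme.
    """

    states: np.ndarray
    actions: np.ndarray
    observations: np.ndarray
    n_action_classes: int
    latents: np.ndarray | None = None
    action_vectors: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        self.actions = np.asarray(self.actions, dtype=np.int64)
        self.observations = np.asarray(self.observations, dtype=np.float64)
        if not (len(self.states) == len(self.actions) == len(self.observations)):
            raise ValueError("states, actions and observations must share length")
        if self.latents is None:
            lat = np.asarray(self.states, dtype=np.float64)
            self.latents = lat[:, None] if lat.ndim == 1 else lat
        else:
            self.latents = np.asarray(self.latents, dtype=np.float64)
            if len(self.latents) != len(self.actions):
                raise ValueError("latents must align with actions")
        if self.action_vectors is not None:
            self.action_vectors = np.asarray(self.action_vectors, dtype=np.float64)
            if len(self.action_vectors) != len(self.actions):
                raise ValueError("action_vectors must align with actions")

    def __len__(self) -> int:
        return len(self.actions)

    @property
    def n_obs_dims(self) -> int:
        return self.observations.shape[1]

    def actions_onehot(self) -> np.ndarray:
        """One-hot encode the action codes, shape (T, n_action_classes)."""
        out = np.zeros((len(self), self.n_action_classes))
        out[np.arange(len(self)), self.actions] = 1.0
        return out

    def action_inputs(self) -> np.ndarray:
        """Action vectors fed to a network: explicit vectors if the
        environment provides them (muscle pulses), else the one-hot codes."""
        if self.action_vectors is not None:
            return self.action_vectors
        return self.actions_onehot()

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        """Write a manifest + columnar arrays + a CSV preview to a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {
            "states": self.states,
            "actions": self.actions,
            "observations": self.observations,
            "latents": self.latents,
        }
        if self.action_vectors is not None:
            arrays["action_vectors"] = self.action_vectors
        np.savez_compressed(directory / "arrays.npz", **arrays)
        manifest = {
            "n_steps": len(self),
            "n_action_classes": int(self.n_action_classes),
            "n_obs_dims": int(self.n_obs_dims),
            "meta": _jsonable(self.meta),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        head = min(len(self), 1000)
        df = pd.DataFrame(
            {
                "t": np.arange(head),
                "state": [np.ravel(s).tolist() for s in self.states[:head]],
                "action": self.actions[:head],
            }
        )
        df.to_csv(directory / "preview.csv", index=False)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "Trajectory":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        with np.load(directory / "arrays.npz") as arr:
            return cls(
                states=arr["states"],
                actions=arr["actions"],
                observations=arr["observations"],
                latents=arr["latents"],
                action_vectors=arr["action_vectors"] if "action_vectors" in arr else None,
                n_action_classes=manifest["n_action_classes"],
                meta=manifest.get("meta", {}),
            )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
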