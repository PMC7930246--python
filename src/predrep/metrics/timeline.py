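"""Learning-trajectory metrics: one record per training checkpoint.

For each stored checkpoint the network is rolled out (frozen weights) on a
shared probe trajectory and the full metric battery is computed: symmetry
axis of the predictive-error curve, latent and observation signal transfer,
participation ratio, intrinsic dimensionality per estimator, and
dimensionality gain.  All stochastic sub-steps (ID subsampling) use fixed
seeds so that recomputing from saved checkpoints reproduces the in-run
timeline exactly.  A metric that fails on one checkpoint is recorded as
NaN with the failure noted; the rest of the timeline continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from predrep.metrics.dimensionality import (
    dimensionality_gain,
    intrinsic_dimension,
    participation_ratio,
)
from predrep.metrics.predictive import predictive_error_curve, symmetry_axis
from predrep.metrics.transfer import pca_scores, signal_transfer
from predrep.trajectory import Trajectory

__all__ = ["TimelineConfig", "MetricTimeline", "build_metric_timeline"]


@dataclass
class TimelineConfig:
    """Conventions shared by every checkpoint evaluation."""

    n_pcs: int = 3
    lags: tuple[int, ...] = tuple(range(-5, 6))
    latent_columns: tuple[int, ...] = (0, 1)
    circular_columns: tuple[int, ...] = ()
    id_methods: tuple[str, ...] = ("mle_k_nn", "correlation_dimension")
    id_subsample: int = 2000
    seed: int = 0


@dataclass
class MetricTimeline:
    records: pd.DataFrame
    config: TimelineConfig
    failures: list[tuple[int, str, str]] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def __getitem__(self, column: str) -> np.ndarray:
        return self.records[column].to_numpy()


def _latent_block(trajectory: Trajectory, config: TimelineConfig) -> np.ndarray:
    cols = []
    for c in config.latent_columns:
        v = trajectory.latents[:, c]
        if c in config.circular_columns:
            cols += [np.cos(v), np.sin(v)]
        else:
            cols.append(v)
    return np.column_stack(cols)


def evaluate_checkpoint(
    net,
    weights: dict,
    probe: Trajectory,
    config: TimelineConfig,
    obs_pcs: np.ndarray | None = None,
    latents: np.ndarray | None = None,
) -> tuple[dict, list[str]]:
    """Full metric battery for one set of frozen weights."""
    rep, outputs = net.rollout(probe, weights=weights)
    if obs_pcs is None:
        obs_pcs = pca_scores(probe.observations, config.n_pcs)
    if latents is None:
        latents = _latent_block(probe, config)
    rec: dict[str, float] = {}
    fails: list[str] = []

    def attempt(name, fn):
        try:
            rec[name] = fn()
        except Exception as err:  # keep the rest of the timeline alive
            rec[name] = np.nan
            fails.append(f"{name}: {err}")

    attempt(
        "symmetry_axis",
        lambda: symmetry_axis(predictive_error_curve(outputs, probe.observations, config.lags))[0],
    )
    attempt("latent_transfer", lambda: signal_transfer(rep, latents, config.n_pcs))
    attempt("observation_transfer", lambda: signal_transfer(rep, obs_pcs, config.n_pcs))
    attempt("pr", lambda: participation_ratio(rep))
    for method in config.id_methods:
        attempt(
            f"id_{method}",
            lambda m=method: intrinsic_dimension(
                rep, m, seed=config.seed, n_max=config.id_subsample
            ).estimate,
        )
    ids = [rec.get(f"id_{m}", np.nan) for m in config.id_methods]
    id_mean = float(np.nanmean(ids)) if np.any(np.isfinite(ids)) else np.nan
    rec["id_mean"] = id_mean
    attempt("dg", lambda: dimensionality_gain(rec["pr"], id_mean))
    return rec, fails


def build_metric_timeline(
    net,
    checkpoints: list[tuple[int, dict]],
    probe: Trajectory,
    config: TimelineConfig | None = None,
) -> MetricTimeline:
    """Evaluate the metric battery at every checkpoint on one probe.

    `checkpoints` is a list of (epoch, weight dict) as produced by the
    model estimators; epochs must be strictly increasing.
    """
    config = config or TimelineConfig()
    epochs = [e for e, _ in checkpoints]
    if any(b <= a for a, b in zip(epochs, epochs[1:])):
        raise ValueError("checkpoint epochs must be strictly increasing")
    obs_pcs = pca_scores(probe.observations, config.n_pcs)
    latents = _latent_block(probe, config)
    rows, failures = [], []
    for epoch, weights in checkpoints:
        rec, fails = evaluate_checkpoint(net, weights, probe, config, obs_pcs, latents)
        rec["epoch"] = epoch
        rows.append(rec)
        failures += [(epoch, name.split(":")[0], name) for name in fails]
    df = pd.DataFrame(rows)
    return MetricTimeline(
        records=df[["epoch"] + [c for c in df.columns if c != "epoch"]],
        config=config,
        failures=failures,
    )
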