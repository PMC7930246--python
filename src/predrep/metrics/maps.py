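"""Tuning maps: place maps over physical space and manifold-cell maps over
the representation's own principal-component coordinates.

A place map bins a probe trajectory's (x, y) positions and averages each
unit's activity per bin — the classic place-field picture.  A manifold-cell
map does the same with the *population's* top-2 PC scores as coordinates:
localized bumps there indicate units tuned to a location on the neural
manifold itself, with no foreign knowledge of the latent variables needed.
Bins visited fewer than `min_occupancy` times are reported as missing
(NaN), never zero-filled.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binned_statistic_2d

from predrep.metrics.transfer import pca_scores

__all__ = ["manifold_cell_maps", "place_maps", "save_map_grid"]


def _binned_maps(
    coords: np.ndarray, activity: np.ndarray, bins: int, min_occupancy: int
) -> np.ndarray:
    if bins < 4:
        raise ValueError("need at least 4 bins per axis")
    counts, xe, ye, binnum = binned_statistic_2d(
        coords[:, 0], coords[:, 1], None, statistic="count", bins=bins, expand_binnumbers=True
    )
    occupied = counts >= min_occupancy
    if not occupied.any():
        raise ValueError("no bin reaches the minimum occupancy")
    n_units = activity.shape[1]
    maps = np.full((n_units, bins, bins), np.nan)
    ix = np.clip(binnum[0] - 1, 0, bins - 1)
    iy = np.clip(binnum[1] - 1, 0, bins - 1)
    flat = ix * bins + iy
    sums = np.zeros((bins * bins, n_units))
    np.add.at(sums, flat, activity)
    cnt = np.bincount(flat, minlength=bins * bins).astype(float)
    with np.errstate(invalid="ignore"):
        means = sums / cnt[:, None]
    means = means.reshape(bins, bins, n_units)
    means[~occupied] = np.nan
    return np.moveaxis(means, -1, 0)


def manifold_cell_maps(
    representation: np.ndarray,
    n_pcs: int = 2,
    bins: int = 16,
    min_occupancy: int = 5,
) -> np.ndarray:
    """Per-unit mean activity binned over the top-2 PC scores.

    Returns (n_units, bins, bins); under-occupied bins are NaN.
    """
    if n_pcs != 2:
        raise ValueError("manifold maps are defined on 2 PC coordinates")
    rep = np.asarray(representation, float)
    scores = pca_scores(rep, 2)
    return _binned_maps(scores, rep, bins, min_occupancy)


def place_maps(
    representation: np.ndarray,
    xy_trace: np.ndarray,
    bins: int = 16,
    min_occupancy: int = 5,
) -> np.ndarray:
    """Per-unit mean activity binned over physical (x, y) coordinates."""
    rep = np.asarray(representation, float)
    xy = np.asarray(xy_trace, float)
    if len(rep) != len(xy) or xy.shape[1] != 2:
        raise ValueError("xy_trace must be (T, 2) aligned with the representation")
    return _binned_maps(xy, rep, bins, min_occupancy)


def save_map_grid(maps: np.ndarray, path, n_cols: int = 10) -> None:
    """Render per-unit tuning maps as a PNG mosaic (one quadrant per unit)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(maps)
    n_rows = int(np.ceil(n / n_cols))
    fig, axes = plt.subplots(n_rows, n_cols, figsize=(1.2 * n_cols, 1.2 * n_rows))
    for i, ax in enumerate(np.atleast_1d(axes).ravel()):
        ax.axis("off")
        if i < n:
            ax.imshow(maps[i].T, origin="lower", interpolation="nearest")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
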