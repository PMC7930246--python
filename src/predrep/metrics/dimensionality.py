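"""Linear and nonlinear dimensionality of a representation manifold.

Participation ratio (PR) is the global, linear measure

    PR = (sum_i lambda_i)^2 / sum_i lambda_i^2

over the eigenvalues of the mean-centered activation covariance: N for an
isotropic N-dimensional cloud, 1 for rank-one data.

Intrinsic dimensionality (ID) is local and nonlinear: for points sampled
from a d-manifold the number of neighbors within radius r scales as r^d at
small r.  Two estimators are provided — the correlation dimension (slope of
the log pair-count curve over a small-radius window) and the Levina-Bickel
k-nearest-neighbor maximum-likelihood estimator — plus a registry for
adding others.  Dimensionality gain DG = PR / mean ID is large when a
representation is globally high-dimensional (curved) but locally
parameterized by few variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "IDEstimate",
    "participation_ratio",
    "intrinsic_dimension",
    "dimensionality_gain",
    "ID_ESTIMATORS",
]


@dataclass
class IDEstimate:
    method: str
    estimate: float
    hyperparams: dict = field(default_factory=dict)
    n_samples: int = 0


def participation_ratio(representation: np.ndarray) -> float:
    """(sum lambda)^2 / sum lambda^2 of the centered covariance spectrum."""
    x = np.asarray(representation, float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    xc = x - x.mean(0)
    s = np.linalg.svd(xc, compute_uv=False)
    lam = s**2 / (len(x) - 1)
    total = lam.sum()
    if total <= 0:
        raise ValueError("zero-variance representation: PR undefined")
    return float(total**2 / np.sum(lam**2))


def _prepare_points(x: np.ndarray, n_max: int, seed: int) -> np.ndarray:
    """Seeded subsample + exact-duplicate pruning (warns if any dropped)."""
    x = np.asarray(x, float)
    if len(x) > n_max:
        rng = np.random.default_rng(seed)
        x = x[rng.choice(len(x), n_max, replace=False)]
    unique = np.unique(x, axis=0)
    if len(unique) < len(x):
        warnings.warn(
            f"pruned {len(x) - len(unique)} duplicate points before ID estimation",
            stacklevel=3,
        )
    return unique


def _mle_knn(x: np.ndarray, k_min: int = 10, k_max: int = 20) -> tuple[float, dict]:
    """Levina-Bickel MLE from k-NN distance ratios, averaged over k."""
    nn = NearestNeighbors(n_neighbors=k_max + 1).fit(x)
    dist, _ = nn.kneighbors(x)
    dist = dist[:, 1:]  # drop self
    logd = np.log(np.clip(dist, 1e-300, None))
    estimates = []
    for k in range(k_min, k_max + 1):
        # inverse mean log-ratio to the k-th neighbor, per point
        denom = logd[:, k - 1][:, None] - logd[:, : k - 1]
        m = (k - 1) / np.sum(denom, axis=1)
        estimates.append(np.mean(m[np.isfinite(m)]))
    return float(np.mean(estimates)), {"k_min": k_min, "k_max": k_max}


def _correlation_dimension(
    x: np.ndarray,
    n_pairs_max: int = 2000,
    c_low: float = 1e-3,
    c_high: float = 0.1,
    n_radii: int = 30,
) -> tuple[float, dict]:
    """Slope of log C(r) vs log r over the small-radius scaling window.

    C(r) is the fraction of point pairs within distance r; the fit window
    keeps radii with c_low <= C(r) <= c_high (widened if too few radii
    qualify), where the r^d scaling of a d-manifold holds.
    """
    if len(x) > n_pairs_max:
        x = x[:: max(1, len(x) // n_pairs_max)][:n_pairs_max]
    d = pdist(x)
    d = d[d > 0]
    radii = np.logspace(
        np.log10(np.quantile(d, 5e-4) + 1e-300), np.log10(np.median(d)), n_radii
    )
    c = np.searchsorted(np.sort(d), radii, side="right") / len(d)
    window = (c >= c_low) & (c <= c_high)
    if window.sum() < 5:
        window = (c > 0) & (c <= max(c_high, 0.3))
    if window.sum() < 2:
        raise ValueError("degenerate geometry: no usable scaling window")
    slope = np.polyfit(np.log(radii[window]), np.log(c[window]), 1)[0]
    return float(slope), {"c_low": c_low, "c_high": c_high, "n_radii": n_radii}


ID_ESTIMATORS = {
    "mle_k_nn": _mle_knn,
    "correlation_dimension": _correlation_dimension,
}


def intrinsic_dimension(
    representation: np.ndarray,
    method: str = "mle_k_nn",
    seed: int = 0,
    n_max: int = 10_000,
    **hyperparams,
) -> IDEstimate:
    """Estimate the manifold dimension of a point cloud.

    Points are subsampled to at most `n_max` with the given seed and exact
    duplicates pruned.  `method` must be registered in ID_ESTIMATORS.
    """
    if method not in ID_ESTIMATORS:
        raise ValueError(f"unknown ID method {method!r}; known: {sorted(ID_ESTIMATORS)}")
    x = _prepare_points(representation, n_max, seed)
    if len(x) < 100:
        raise ValueError("need at least 100 distinct points")
    estimate, used = ID_ESTIMATORS[method](x, **hyperparams)
    return IDEstimate(method=method, estimate=estimate, hyperparams=used, n_samples=len(x))


def dimensionality_gain(pr: float, id_mean: float) -> float:
    """DG = PR / ID, with ID the mean over the computed estimators."""
    if id_mean <= 0:
        raise ValueError("id_mean must be positive")
    return float(pr / id_mean)
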