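"""Signal transfer: canonical correlation between representation PCs and
a covariate block.

Latent signal transfer projects the unit-activation matrix onto its top
principal components (mean-centered, unscaled) and measures the mean
canonical correlation against the latent variables; a value of 1 means the
latents are fully linearly decodable from those PCs.  The observation-space
variant replaces the latents with the top PCs of the observation stream.
Both blocks get a small relative ridge for numerical stability.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

__all__ = ["pca_scores", "canonical_correlations", "signal_transfer"]


def pca_scores(
    x: np.ndarray, n_pcs: int, pc_range: tuple[int, int] | None = None
) -> np.ndarray:
    """Scores on the top principal components (mean-centered, unscaled).

    `pc_range` = (i, j) selects PCs i..j with 1-based inclusive indexing
    (e.g. (4, 5) for the fourth and fifth components); otherwise the first
    `n_pcs` are used.
    """
    x = np.asarray(x, float)
    xc = x - x.mean(0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    if pc_range is not None:
        i, j = pc_range
        return u[:, i - 1 : j] * s[i - 1 : j]
    return u[:, :n_pcs] * s[:n_pcs]


def _inv_sqrt(cov: np.ndarray, ridge: float) -> np.ndarray:
    cov = cov + ridge * np.trace(cov) / max(len(cov), 1) * np.eye(len(cov))
    vals, vecs = linalg.eigh(cov)
    vals = np.clip(vals, 1e-30, None)
    return vecs @ np.diag(vals**-0.5) @ vecs.T


def canonical_correlations(
    x: np.ndarray, y: np.ndarray, ridge: float = 1e-6
) -> np.ndarray:
    """Canonical correlations between two centered blocks (descending).

    Computed from the whitened cross-covariance; the number of returned
    correlations is the minimum of the two block dimensions.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    if len(x) != len(y):
        raise ValueError("blocks must share the sample axis")
    if len(x) <= max(x.shape[1], y.shape[1]):
        raise ValueError("need more samples than dimensions")
    xc = x - x.mean(0)
    yc = y - y.mean(0)
    n = len(xc)
    sxx = xc.T @ xc / n
    syy = yc.T @ yc / n
    sxy = xc.T @ yc / n
    m = _inv_sqrt(sxx, ridge) @ sxy @ _inv_sqrt(syy, ridge)
    corrs = linalg.svdvals(m)
    return np.clip(corrs, 0.0, 1.0)


def signal_transfer(
    representation: np.ndarray,
    variables: np.ndarray,
    n_pcs: int = 3,
    pc_range: tuple[int, int] | None = None,
    ridge: float = 1e-6,
) -> float:
    """Mean canonical correlation between representation PCs and a block.

    `variables` may be any aligned covariate block: latent coordinates,
    a (cos, sin) pair for a circular variable, or top PCs of the
    observations.
    """
    scores = pca_scores(representation, n_pcs, pc_range)
    return float(np.mean(canonical_correlations(scores, variables, ridge)))
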