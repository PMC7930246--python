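"""Linear decoding of latent variables at a time lag.

Fits a ridge readout from the representation at time t to each latent
variable at time t + lag, on a training half of the probe, and reports the
held-out root-mean-square error per lag.  A curve whose minimum lies at a
positive lag means the representation codes future latent states better
than past ones.  Circular variables are decoded through their (cos, sin)
pair and scored by wrapped angular error.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import Ridge

__all__ = ["lag_decoding"]


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def lag_decoding(
    representation: np.ndarray,
    latent_trace: np.ndarray,
    lags=range(-5, 6),
    circular: tuple[int, ...] = (),
    alpha: float = 1e-2,
) -> dict[int, np.ndarray]:
    """Held-out RMS decoding error per lag per latent variable.

    Returns {variable index: array of RMS over lags}.  `circular` lists
    latent columns that are angles (decoded via sine/cosine, errors on the
    circle).  Ridge regularization keeps rank-deficient representations
    well-posed.
    """
    r = np.asarray(representation, float)
    z = np.asarray(latent_trace, float)
    if z.ndim == 1:
        z = z[:, None]
    if len(r) != len(z):
        raise ValueError("representation and latents must be aligned")
    lags = list(lags)
    T = len(r)
    out = {v: np.full(len(lags), np.nan) for v in range(z.shape[1])}
    for li, lag in enumerate(lags):
        lo, hi = max(0, -lag), min(T, T - lag)
        if hi - lo < 10:
            continue
        x = r[lo:hi]
        y = z[lo + lag : hi + lag]
        half = (hi - lo) // 2
        for v in range(z.shape[1]):
            if v in circular:
                tgt = np.column_stack([np.cos(y[:, v]), np.sin(y[:, v])])
                model = Ridge(alpha=alpha).fit(x[:half], tgt[:half])
                pred = model.predict(x[half:])
                ang = np.arctan2(pred[:, 1], pred[:, 0])
                err = _wrap(ang - y[half:, v])
            else:
                model = Ridge(alpha=alpha).fit(x[:half], y[:half, v])
                err = model.predict(x[half:]) - y[half:, v]
            out[v][li] = float(np.sqrt(np.mean(err**2)))
    return out
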