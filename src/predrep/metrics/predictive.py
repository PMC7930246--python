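"""Lag-resolved predictive error and its symmetry axis.

The predictive error at lag L is the mean squared distance between the
network's output at time t and the observation at time t+L:

    C(L) = mean_t || o_{t+L} - y_t ||^2

A curve whose minimum (and symmetry axis) sits near L = +1 indicates the
output tracks the *upcoming* observation — genuine prediction — while an
autoencoder's curve is symmetric about L = 0.  The baseline curve replaces
y_t with o_t (observation self-similarity), which is symmetric about 0 by
construction and calibrates how much structure the lag profile owes to
temporal correlation in the observations themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PredictiveErrorCurve", "predictive_error_curve", "symmetry_axis"]


@dataclass
class PredictiveErrorCurve:
    lags: np.ndarray  # integer lags
    values: np.ndarray  # mean squared error per lag; NaN if lag had no overlap
    baseline: np.ndarray  # observation self-similarity per lag


def _lagged_mse(a: np.ndarray, b: np.ndarray, lag: int) -> float:
    """mean_t ||b_{t+lag} - a_t||^2 over the valid overlap; NaN if empty."""
    T = len(a)
    lo, hi = max(0, -lag), min(T, T - lag)
    if hi <= lo:
        return np.nan
    diff = b[lo + lag : hi + lag] - a[lo:hi]
    return float(np.mean(np.sum(diff**2, axis=1)))


def predictive_error_curve(
    outputs: np.ndarray, observations: np.ndarray, lags=range(-5, 6)
) -> PredictiveErrorCurve:
    """Mean L2 error between outputs and lag-shifted observations.

    Edge steps without a valid lag partner are excluded, not padded.
    """
    outputs = np.atleast_2d(np.asarray(outputs, float))
    observations = np.atleast_2d(np.asarray(observations, float))
    if len(outputs) != len(observations):
        raise ValueError("outputs and observations must be time-aligned")
    lags = np.asarray(list(lags), dtype=int)
    values = np.array([_lagged_mse(outputs, observations, L) for L in lags])
    baseline = np.array([_lagged_mse(observations, observations, L) for L in lags])
    return PredictiveErrorCurve(lags=lags, values=values, baseline=baseline)


def symmetry_axis(
    curve: PredictiveErrorCurve | tuple[np.ndarray, np.ndarray],
    resolution: float = 0.05,
    min_overlap: int = 3,
) -> tuple[float, bool]:
    """Axis about which the error curve is most mirror-symmetric.

    Scans candidate axes on a `resolution`-spaced grid across the lag range
    and, for each, measures the mean squared difference between the curve
    and its reflection (linearly interpolated at non-integer reflected
    positions; only lags whose reflection falls inside the range count, and
    candidates with fewer than `min_overlap` such lags are excluded).
    Returns (axis, degenerate_flag); ties break toward 0, and a flat curve
    returns (0.0, True).
    """
    if isinstance(curve, PredictiveErrorCurve):
        lags, values = curve.lags, curve.values
    else:
        lags, values = curve
    lags = np.asarray(lags, float)
    values = np.asarray(values, float)
    ok = np.isfinite(values)
    lags, values = lags[ok], values[ok]
    if len(lags) < 3:
        raise ValueError("need at least 3 lags")
    if np.ptp(values) == 0:
        return 0.0, True
    lo, hi = lags.min(), lags.max()
    candidates = np.arange(lo, hi + resolution / 2, resolution)
    best_axis, best_cost = 0.0, np.inf
    for c in candidates:
        reflected = 2 * c - lags
        inside = (reflected >= lo) & (reflected <= hi)
        if inside.sum() < min_overlap:
            continue
        interp = np.interp(reflected[inside], lags, values)
        cost = float(np.mean((values[inside] - interp) ** 2))
        if cost < best_cost - 1e-15 or (
            abs(cost - best_cost) <= 1e-15 and abs(c) < abs(best_axis)
        ):
            best_cost, best_axis = cost, float(c)
    return best_axis, False
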