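"""Session-signal smoothing and characteristic-value extraction.

The smoother is a sliding-window local linear least-squares filter: each
output sample is the value, at the window center, of the degree-1 polynomial
fitted by least squares over a centered window.  For a symmetric window the
slope basis is orthogonal to the constant basis, so the fitted center value
equals the window mean; edges shrink to the largest symmetric window that
fits, leaving the two endpoint samples untouched.

Feature extraction follows the e-nose convention: once the headspace signal
has stabilized, take the stable (plateau), average and maximum values per
channel as the characteristic signal values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NotStabilizedError, ParameterError
from .types import SENSOR_RANGES, FeatureVector, SensorSession

__all__ = [
    "lls_filter",
    "trailing_linear_smooth",
    "extract_features",
    "minmax_scale",
    "minmax_unscale",
    "StableRule",
]


def lls_filter(signal: np.ndarray, window: int = 11) -> np.ndarray:
    """Local linear least-squares smoothing with a shrinking-window edge policy.

    Parameters
    ----------
    signal : 1-D array
    window : odd window length, 3 <= window <= len(signal)

    Returns
    -------
    Smoothed signal of the same length.  Exactly reproduces affine inputs
    (a degree-1 fit is exact on lines) and is linear in the input.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ParameterError("signal must be 1-D")
    n = len(x)
    if window % 2 == 0:
        raise ParameterError(f"window must be odd, got {window}")
    if not 3 <= window <= n:
        raise ParameterError(f"window must satisfy 3 <= window <= {n}, got {window}")
    half = window // 2
    # symmetric-window degree-1 LS center value == window mean; use cumsums
    csum = np.concatenate(([0.0], np.cumsum(x)))
    out = np.empty(n)
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo = idx - h
    hi = idx + h
    out = (csum[hi + 1] - csum[lo]) / (2 * h + 1)
    return out


def trailing_linear_smooth(signal: np.ndarray, window: int = 5) -> np.ndarray:
    """Causal local linear least-squares smoothing.

    Each output sample is the endpoint value of a degree-1 least-squares fit
    over the trailing ``window`` samples (shrinking at the start; samples
    with fewer than 3 points pass through).  Unlike the symmetric
    :func:`lls_filter`, this estimator uses no future samples, so it can
    denoise the most recent observations of a running series — e.g. the seed
    window of a recursive forecast.
    """
    v = np.asarray(signal, dtype=float)
    if v.ndim != 1:
        raise ParameterError("signal must be 1-D")
    if window < 1:
        raise ParameterError("window must be >= 1")
    out = v.copy()
    for i in range(len(v)):
        lo = max(0, i - window + 1)
        m = i - lo + 1
        if m < 3:
            continue
        t = np.arange(m, dtype=float)
        y = v[lo : i + 1]
        tc = t - t.mean()
        slope = float(np.dot(tc, y) / np.dot(tc, tc))
        out[i] = y.mean() + slope * tc[-1]
    return out


@dataclass(frozen=True)
class StableRule:
    """Stability acceptance rule for the plateau feature.

    tail_frac:        final fraction of the session averaged into the stable value
    slope_window_frac: final fraction of the session over which the rolling
                      slope is estimated (longer than the tail so the noise
                      on the slope estimate stays well below the tolerance)
    slope_tol_frac:   maximum |slope| of the linear fit over that window,
                      as a fraction of the channel's measuring range per minute
    """

    tail_frac: float = 0.10
    slope_window_frac: float = 0.30
    slope_tol_frac: float = 0.005

    def __post_init__(self):
        if not 0 < self.tail_frac <= 1:
            raise ParameterError("tail_frac must lie in (0, 1]")
        if not self.tail_frac <= self.slope_window_frac <= 1:
            raise ParameterError("slope_window_frac must lie in [tail_frac, 1]")
        if self.slope_tol_frac <= 0:
            raise ParameterError("slope_tol_frac must be positive")


def _tail_slope(t: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope (units per second) of y over t."""
    t0 = t - t.mean()
    denom = float(np.dot(t0, t0))
    if denom == 0:
        return 0.0
    return float(np.dot(t0, y - y.mean()) / denom)


def extract_features(session: SensorSession, stable_rule: StableRule | None = None) -> FeatureVector:
    """Characteristic values (stable, average, maximum) per channel.

    The stable value is the mean of the final ``tail_frac`` of samples and is
    accepted only if the rolling slope over that tail is below
    ``slope_tol_frac`` of the channel's measuring range per minute; a channel
    that never stabilizes raises :class:`NotStabilizedError` naming it.
    Average and maximum are taken over the full session.
    """
    rule = stable_rule or StableRule()
    n = session.n_samples
    k = max(int(np.ceil(rule.tail_frac * n)), 2)
    ks = max(int(np.ceil(rule.slope_window_frac * n)), k)
    stable, mean, mx = {}, {}, {}
    for gas, y in session.channels.items():
        lo, hi = SENSOR_RANGES.get(gas, (float(np.min(y)), float(np.max(y))))
        tol_per_s = rule.slope_tol_frac * (hi - lo) / 60.0
        slope = _tail_slope(session.time[-ks:], y[-ks:])
        if abs(slope) > tol_per_s:
            raise NotStabilizedError(
                gas,
                f"channel {gas!r} did not stabilize: tail slope {slope:.4g}/s "
                f"exceeds tolerance {tol_per_s:.4g}/s",
            )
        stable[gas] = float(np.mean(y[-k:]))
        mean[gas] = float(np.mean(y))
        mx[gas] = float(np.max(y))
    return FeatureVector(stable=stable, mean=mean, max=mx)


def minmax_scale(values, lo: float, hi: float) -> np.ndarray:
    """Map values affinely so that lo -> 0 and hi -> 1.

    lo/hi must come from training data only; hi must exceed lo.
    """
    if not hi > lo:
        raise ParameterError(f"degenerate range: hi ({hi}) must exceed lo ({lo})")
    return (np.asarray(values, dtype=float) - lo) / (hi - lo)


def minmax_unscale(scaled, lo: float, hi: float) -> np.ndarray:
    """Exact inverse of :func:`minmax_scale`."""
    if not hi > lo:
        raise ParameterError(f"degenerate range: hi ({hi}) must exceed lo ({lo})")
    return np.asarray(scaled, dtype=float) * (hi - lo) + lo
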