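"""Hurst-exponent estimation: adaptive fractal analysis (AFA) and DFA.

AFA estimates H from the scaling of residual fluctuations around a
*globally smooth* trend.  The series is first integrated into its
random-walk profile (as in DFA, so that a stationary fGn input with Hurst
exponent H yields a fluctuation exponent of H, and an fBm input yields
H + 1).  The profile is covered by overlapping windows of odd length
w = 2n + 1 that step by n points, a low-order polynomial is least-squares
fitted in each window, and consecutive local fits y¹, y² are blended over
their n + 1 shared points with linearly varying weights

    v(i) = (1 − l/n) · y¹(i) + (l/n) · y²(i),   l = 0..n,

giving one continuous global trend v.  The fluctuation at window size w is

    F(w) = sqrt( (1/N) Σᵢ (u(i) − v(i))² ) ~ w^H,

and H is the slope of log₂ F(w) against log₂ w over the configured window
grid (default n = 5..13, i.e. w = 11..27, suited to series of a few
hundred samples).

DFA (the classical per-box variant) is provided as the independent
cross-check used for fGn/fBm signal classification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .timeseries import TimeSeries

__all__ = [
    "AFAResult",
    "DEFAULT_N_LIST",
    "afa_trend",
    "afa_fluctuation",
    "fit_hurst",
    "afa_hurst",
    "dfa",
]

DEFAULT_N_LIST: tuple[int, ...] = tuple(range(5, 14))  # w = 11, 13, ..., 27


@dataclass
class AFAResult:
    """Window sizes, fluctuation function and (once fitted) H."""

    window_sizes: np.ndarray
    fluctuations: np.ndarray
    hurst: float | None = None
    log_intercept: float | None = None
    r_squared: float | None = None
    trend_order: int = 2
    method: str = "afa"

    def __post_init__(self):
        w = np.asarray(self.window_sizes, dtype=int)
        f = np.asarray(self.fluctuations, dtype=float)
        if w.shape != f.shape or w.ndim != 1:
            raise ValueError("window_sizes and fluctuations must match 1-D")
        if np.any(np.diff(w) <= 0):
            raise ValueError("window_sizes must be strictly increasing")
        if np.any(f < 0):
            raise ValueError("fluctuations must be nonnegative")
        self.window_sizes, self.fluctuations = w, f


def _hat_matrix(w: int, order: int) -> np.ndarray:
    """Least-squares projection onto polynomials of degree ``order`` on a
    window of length ``w`` (centered abscissa for conditioning)."""
    t = np.arange(w, dtype=float) - (w - 1) / 2.0
    design = np.vander(t, order + 1, increasing=True)
    return design @ np.linalg.pinv(design)


def _afa_trend_values(x: np.ndarray, w: int, order: int) -> np.ndarray:
    n_half = (w - 1) // 2
    n_samples = x.size
    if w % 2 == 0:
        raise ValueError("window size must be odd (w = 2n + 1)")
    if w < 2 * order + 2:
        raise ValueError(f"window size {w} too small for polynomial order {order}")
    if w >= n_samples:
        raise ValueError(f"window size {w} must be smaller than the series ({n_samples})")

    starts = list(range(0, n_samples - w + 1, n_half))
    if starts[-1] != n_samples - w:
        # tail shorter than a full window: extend the last window backward
        # so it ends exactly at the final sample
        starts.append(n_samples - w)

    windows = np.stack([x[s:s + w] for s in starts])
    fits = windows @ _hat_matrix(w, order).T

    trend = np.empty(n_samples)
    trend[starts[0]:starts[0] + w] = fits[0]
    prev_end = starts[0] + w
    for k in range(1, len(starts)):
        s = starts[k]
        overlap = prev_end - s  # n+1 for regular steps, longer for the tail
        if overlap >= 2:
            wt = np.linspace(0.0, 1.0, overlap)
            trend[s:prev_end] = (1.0 - wt) * trend[s:prev_end] + wt * fits[k][:overlap]
        trend[prev_end:s + w] = fits[k][overlap:]
        prev_end = s + w
    return trend


def afa_trend(ts: TimeSeries, w: int, order: int = 2) -> TimeSeries:
    """Globally stitched smooth trend v(i) of the input at window size w.

    Applies the overlap-and-blend construction described in the module
    docstring directly to ``ts`` (no integration here; callers working on
    raw noise-like signals integrate first, which is what
    :func:`afa_fluctuation` does).
    """
    return ts.with_values(_afa_trend_values(ts.values, int(w), int(order)))


def afa_fluctuation(ts: TimeSeries, n_list: Iterable[int] = DEFAULT_N_LIST,
                    order: int = 2, integrate: bool = True) -> AFAResult:
    """Fluctuation function F(w) over the window grid w = 2n + 1.

    The series is integrated into its mean-removed random-walk profile
    before detrending (``integrate=False`` analyses the raw values, for
    signals that are already walk-like).
    """
    n_list = sorted(int(n) for n in n_list)
    if not n_list or n_list[0] < 1:
        raise ValueError("n_list must contain positive integers")
    x = ts.values
    if np.ptp(x) == 0.0:
        # exactly constant input: the profile is identically zero, so the
        # fluctuation function is zero at every window (fit_hurst then
        # reports the degeneracy instead of returning NaN)
        w = np.array([2 * n + 1 for n in n_list])
        return AFAResult(w, np.zeros(w.size), trend_order=order, method="afa")
    if integrate:
        x = np.cumsum(x - x.mean())
    ws, fs = [], []
    for n in n_list:
        w = 2 * n + 1
        v = _afa_trend_values(x, w, order)
        fs.append(float(np.sqrt(np.mean((x - v) ** 2))))
        ws.append(w)
    return AFAResult(np.array(ws), np.array(fs), trend_order=order, method="afa")


def fit_hurst(result: AFAResult) -> AFAResult:
    """H as the OLS slope of log₂ F(w) on log₂ w; r² recorded."""
    if np.any(result.fluctuations <= 0):
        raise ValueError(
            "fluctuation function has zero values (degenerate, e.g. constant "
            "input); no scaling exponent is defined")
    logw = np.log2(result.window_sizes.astype(float))
    logf = np.log2(result.fluctuations)
    slope, intercept = np.polyfit(logw, logf, 1)
    resid = logf - (slope * logw + intercept)
    sst = np.sum((logf - logf.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 1.0
    return replace(result, hurst=float(slope), log_intercept=float(intercept),
                   r_squared=float(r2))


def afa_hurst(ts: TimeSeries, n_list: Iterable[int] = DEFAULT_N_LIST,
              order: int = 2) -> AFAResult:
    """Convenience: fluctuation function plus fitted H in one call."""
    return fit_hurst(afa_fluctuation(ts, n_list=n_list, order=order))


def default_box_sizes(n_samples: int, order: int = 1,
                      n_sizes: int = 12) -> np.ndarray:
    """Log-spaced DFA box sizes from 10 up to N/8.

    Boxes below ~10 samples carry the well-documented polynomial-fit bias
    of small scales; above N/8 fewer than 8 boxes enter the RMS and the
    fluctuation estimate itself becomes biased.
    """
    lo = max(10, order + 2)
    hi = n_samples // 8
    if hi <= lo:
        raise ValueError(f"series too short for DFA (N = {n_samples})")
    sizes = np.unique(np.geomspace(lo, hi, n_sizes).round().astype(int))
    return sizes


def dfa(ts: TimeSeries, box_sizes: Sequence[int] | None = None,
        order: int = 1) -> AFAResult:
    """Classical detrended fluctuation analysis.

    Cumulative-sum profile, non-overlapping boxes, per-box polynomial
    detrend of degree ``order`` (default 1), RMS fluctuation per box size,
    exponent from the log-log OLS slope.  For fGn the exponent estimates
    H; for fBm it estimates H + 1.
    """
    x = ts.values
    n_samples = x.size
    if box_sizes is None:
        box_sizes = default_box_sizes(n_samples, order)
    box_sizes = np.asarray(sorted(set(int(s) for s in box_sizes)))
    if box_sizes[0] < order + 2:
        raise ValueError(f"box sizes must be >= order + 2 = {order + 2}")
    if box_sizes[-1] > n_samples // 4:
        raise ValueError("largest box exceeds N/4")

    profile = np.cumsum(x - x.mean())
    flucts = np.empty(box_sizes.size)
    for i, s in enumerate(box_sizes):
        n_boxes = n_samples // s
        segs = profile[:n_boxes * s].reshape(n_boxes, s)
        resid = segs - segs @ _hat_matrix(s, order).T
        flucts[i] = np.sqrt(np.mean(resid**2))
    result = AFAResult(box_sizes, flucts, trend_order=order, method="dfa")
    return fit_hurst(result)
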