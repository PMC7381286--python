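"""Power-spectrum estimation and the scale-invariance screen.

Scale-free signals have a power-law spectrum S(f) ≈ C·|f|^{−β}; β is read
off as the negative slope of an ordinary least-squares fit of log power on
log frequency, by default over the low-frequency band below 0.1 Hz where
the power-law approximation is best and where the neurally driven part of
the BOLD signal lives.  A signal is treated as scale-invariant (and hence
eligible for fractal classification) only when −1 < β < 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .timeseries import TimeSeries

__all__ = [
    "PSDEstimate",
    "periodogram",
    "welch_psd",
    "fit_beta",
    "scale_invariance_gate",
    "BETA_LOWER",
    "BETA_UPPER",
]

BETA_LOWER = -1.0
BETA_UPPER = 3.0


@dataclass
class PSDEstimate:
    """Spectrum plus, once fitted, the power-law parameters (C, β).

    ``power`` is a variance decomposition: the powers at the positive
    Fourier frequencies sum to the series variance (Parseval).  ``beta``
    and friends stay ``None`` until :func:`fit_beta` is applied.
    """

    frequencies: np.ndarray
    power: np.ndarray
    beta: float | None = None
    log_intercept: float | None = None
    fit_band: tuple[float, float] | None = None
    r_squared: float | None = None

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape or f.ndim != 1:
            raise ValueError("frequencies and power must be equal-length 1-D")
        if np.any(np.diff(f) <= 0) or np.any(f <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        if np.any(p < 0):
            raise ValueError("power must be nonnegative")
        self.frequencies, self.power = f, p


def periodogram(ts: TimeSeries) -> PSDEstimate:
    """Raw periodogram at the Fourier frequencies k/(N·Δt), k = 1..⌊N/2⌋.

    The mean (zero-frequency component) is removed; the remaining powers
    sum exactly to the biased sample variance of the series.
    """
    if ts.n < 8:
        raise ValueError("periodogram needs at least 8 samples")
    x = ts.values - ts.values.mean()
    n = ts.n
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=ts.sampling_interval)
    power = (2.0 / n**2) * np.abs(spec) ** 2
    if n % 2 == 0:  # Nyquist bin is not doubled
        power[-1] /= 2.0
    return PSDEstimate(freqs[1:], power[1:])


def welch_psd(ts: TimeSeries, nperseg: int | None = None) -> PSDEstimate:
    """Welch-averaged spectrum (variance-reduced alternative to the raw
    periodogram); zero frequency dropped."""
    from scipy.signal import welch

    if ts.n < 8:
        raise ValueError("welch_psd needs at least 8 samples")
    if nperseg is None:
        nperseg = max(8, ts.n // 4)
    freqs, power = welch(ts.values, fs=1.0 / ts.sampling_interval,
                         nperseg=nperseg, detrend="constant")
    keep = freqs > 0
    return PSDEstimate(freqs[keep], power[keep])


def default_fit_band(psd: PSDEstimate, upper: float = 0.1) -> tuple[float, float]:
    """Lowest Fourier frequency up to ``upper`` Hz (or the full range when
    the series is sampled too slowly to reach 0.1 Hz usefully)."""
    lo = psd.frequencies[0]
    hi = min(upper, psd.frequencies[-1])
    if hi <= lo:
        hi = psd.frequencies[-1]
    return (lo, hi)


def fit_beta(psd: PSDEstimate, fit_band: tuple[float, float] | None = None,
             min_points: int = 6) -> PSDEstimate:
    """OLS fit of log S(f) = log C − β·log f inside ``fit_band``.

    Returns a new estimate with ``beta`` (negative slope), the fitted
    ``log_intercept`` (natural-log C) and the in-band r².  Frequencies with
    zero power are dropped with a warning (their log is undefined).
    """
    if fit_band is None:
        fit_band = default_fit_band(psd)
    lo, hi = fit_band
    if not (0 < lo < hi):
        raise ValueError("fit_band must be a positive-width interval")
    in_band = (psd.frequencies >= lo) & (psd.frequencies <= hi)
    f = psd.frequencies[in_band]
    p = psd.power[in_band]
    if np.any(p == 0):
        warnings.warn("dropping zero-power frequencies from the spectral fit")
        f, p = f[p > 0], p[p > 0]
    if f.size < min_points:
        raise ValueError(
            f"need at least {min_points} in-band frequencies, got {f.size}")
    logf, logp = np.log(f), np.log(p)
    slope, intercept = np.polyfit(logf, logp, 1)
    resid = logp - (slope * logf + intercept)
    sst = np.sum((logp - logp.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 1.0
    return replace(psd, beta=-slope, log_intercept=intercept,
                   fit_band=(float(lo), float(hi)), r_squared=float(r2))


def scale_invariance_gate(psd: PSDEstimate) -> tuple[bool, dict]:
    """Screen for power-law scale invariance: pass iff −1 < β < 3 (strict).

    Returns the verdict together with a small report (β, band, r²).
    """
    if psd.beta is None:
        raise ValueError("fit_beta must be applied before gating")
    passed = bool(BETA_LOWER < psd.beta < BETA_UPPER)
    report = {"beta": float(psd.beta), "fit_band": psd.fit_band,
              "r_squared": psd.r_squared, "passed": passed}
    return passed, report
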