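"""Uniformly sampled one-dimensional signals.

The central container of the package: a BOLD ROI time series u(i),
i = 1..N, sampled every ``sampling_interval`` seconds (the scanner TR for
volume series).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeSeries"]


@dataclass
class TimeSeries:
    """A uniformly sampled 1-D signal.

    Parameters
    ----------
    values
        Ordered sample values u(1)..u(N); coerced to a float array.
    sampling_interval
        Time between consecutive samples, in seconds (TR = 2.0 s for the
        volume series this package targets).
    label
        Free-text identifier, e.g. ``"sub-012__ACC"``.
    """

    values: np.ndarray
    sampling_interval: float = 2.0
    label: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if values.size < 2:
            raise ValueError("TimeSeries needs at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("TimeSeries values must be finite")
        if not (self.sampling_interval > 0 and np.isfinite(self.sampling_interval)):
            raise ValueError("sampling_interval must be a positive finite number")
        self.values = values
        self.sampling_interval = float(self.sampling_interval)

    @property
    def n(self) -> int:
        """Number of samples N."""
        return self.values.size

    @property
    def nyquist(self) -> float:
        """Nyquist frequency 1/(2 Δt) in Hz."""
        return 0.5 / self.sampling_interval

    @property
    def times(self) -> np.ndarray:
        """Sample times i·Δt, starting at 0."""
        return np.arange(self.n) * self.sampling_interval

    def with_values(self, values, label: str | None = None) -> "TimeSeries":
        """Return a new series with the same metadata but new values."""
        return TimeSeries(values, self.sampling_interval,
                          self.label if label is None else label)
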