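"""Uniformly sampled scalar time series.

The single in-memory carrier used throughout the package for control
signals, perceptual quantities, accumulator activations and disturbances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["UniformSeries"]


@dataclass
class UniformSeries:
    """A scalar signal sampled on a uniform time grid.

    Parameters
    ----------
    t0 : float
        Time of the first sample, in seconds.
    dt : float
        Sample interval, in seconds. Must be positive.
    values : numpy.ndarray
        Sample values, one-dimensional.
    """

    t0: float
    dt: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"sample interval must be positive, got {self.dt}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Sample times ``t0 + j*dt``."""
        return self.t0 + self.dt * np.arange(len(self.values))

    @property
    def duration(self) -> float:
        """Time spanned from the first to the last sample."""
        return self.dt * (len(self.values) - 1)

    def index_of(self, t: float) -> int:
        """Index of the sample nearest to time ``t``."""
        j = int(round((t - self.t0) / self.dt))
        if not 0 <= j < len(self.values):
            raise IndexError(f"time {t} outside series range")
        return j

    def at(self, t) -> np.ndarray | float:
        """Linear interpolation at arbitrary times (clamped at the ends)."""
        return np.interp(t, self.times, self.values)

    def copy(self) -> "UniformSeries":
        return UniformSeries(self.t0, self.dt, self.values.copy())

    def same_grid(self, other: "UniformSeries", tol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and abs(self.t0 - other.t0) <= tol
            and abs(self.dt - other.dt) <= tol
        )
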