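"""Scalar time series: sea level and global CO₂.

Times are in ka before present (kyr BP), increasing into the past, on
1k-year steps for the analysis times.  Values between tabulated times
are linearly interpolated; queries outside the tabulated coverage raise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ScalarSeries:
    time_ka: np.ndarray
    value: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_ka, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size == 0:
            raise ValueError("time and value must be equal-length 1-D arrays")
        order = np.argsort(t)
        object.__setattr__(self, "time_ka", t[order])
        object.__setattr__(self, "value", v[order])

    def at(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < self.time_ka[0] - 1e-9) or np.any(t > self.time_ka[-1] + 1e-9):
            raise ValueError(
                f"time {t} outside series coverage "
                f"[{self.time_ka[0]}, {self.time_ka[-1]}] ka"
            )
        return np.interp(t, self.time_ka, self.value)

    def to_frame(self, value_name):
        return pd.DataFrame({"time_ka": self.time_ka, value_name: self.value})


class SeaLevelSeries(ScalarSeries):
    """Sea level s(t) in metres relative to present; s(0) = 0 when covered."""

    def __post_init__(self):
        super().__post_init__()
        if self.time_ka[0] <= 0.0 <= self.time_ka[-1] and abs(self.at(0.0)) > 1e-6:
            raise ValueError("sea level at present day must be 0 m")


class CO2Series(ScalarSeries):
    """Global CO₂ in ppm; strictly positive."""

    def __post_init__(self):
        super().__post_init__()
        if np.any(self.value <= 0):
            raise ValueError("CO2 concentrations must be strictly positive")


def read_scalar_csv(path, cls=ScalarSeries, value_col=None):
    """Read a two-column (time_ka, value) CSV into a series object."""
    df = pd.read_csv(path)
    if value_col is None:
        value_col = [c for c in df.columns if c != "time_ka"][0]
    return cls(time_ka=df["time_ka"].to_numpy(), value=df[value_col].to_numpy())
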