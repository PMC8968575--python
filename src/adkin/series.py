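"""The measured-series container shared by every layer of the toolkit."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeSeries"]


@dataclass(frozen=True)
class TimeSeries:
    """A batch-assay time series: paired (time, value) measurements.

    ``times`` are in days, strictly increasing and non-negative; ``values``
    are cumulative measurements in the unit named by ``unit`` (e.g. "L",
    "mL/g_VS", "g_COD/L" — free text, carried along but never interpreted).
    """

    times: np.ndarray
    values: np.ndarray
    unit: str = "arbitrary"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(t) < 2:
            raise ValueError("a series needs at least 2 points")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Total assay duration (final time point, d)."""
        return float(self.times[-1])

    def truncated(self, cutoff: float) -> "TimeSeries":
        """The sub-series with time ≤ cutoff (inclusive)."""
        mask = self.times <= cutoff
        if mask.sum() < 2:
            raise ValueError(f"fewer than 2 points at or before t={cutoff}")
        return TimeSeries(self.times[mask], self.values[mask], self.unit)
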