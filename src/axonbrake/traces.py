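"""Uniformly sampled rate/signal traces and event trains, with text I/O.

All times are in milliseconds; firing rates are in Hz. A :class:`RateTrace`
is the common currency between the synthetic-input generators, the release
simulator and the ex vivo analysis helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RateTrace", "EventTrain", "read_trace", "write_trace"]


@dataclass(frozen=True)
class RateTrace:
    """A uniformly sampled, non-negative time series.

    Parameters
    ----------
    dt:
        Sample interval in ms (> 0).
    values:
        Rate (Hz) or normalized signal samples; finite and >= 0.
    label:
        Free-text description carried through the pipeline.
    """

    dt: float
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.any(self.values < 0):
            raise ValueError("rate/signal values must be >= 0")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms, starting at 0."""
        return np.arange(self.values.size) * self.dt

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    def with_values(self, values: np.ndarray, label: str | None = None) -> "RateTrace":
        return RateTrace(self.dt, values, self.label if label is None else label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times, "value": self.values})


@dataclass(frozen=True)
class EventTrain:
    """Sorted event times (ms); ``kind`` distinguishes spikes from stimuli."""

    times: np.ndarray
    kind: str = "stimulus"
    label: str = ""

    _KINDS = ("spike", "stimulus")

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        t = self.times
        if t.ndim != 1:
            raise ValueError("times must be 1-D")
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be non-negative and strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def write_trace(path, trace: RateTrace) -> None:
    """Write a trace as two-column tab-delimited text with a header line."""
    trace.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_trace(path, label: str = "") -> RateTrace:
    """Read a two-column (time_ms, value) delimited text file.

    The time column must be uniform and start at 0; dt is inferred.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_ms, value)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples to infer dt")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time grid is not uniform")
    if abs(t[0]) > 1e-9:
        raise ValueError(f"{path}: time axis must start at 0")
    return RateTrace(float(steps[0]), v, label=label or str(path))
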