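"""Dopamine release-uptake impulse response and the drive-to-[DA]_o map.

Extracellular dopamine after a single stimulus rises within a few ms and is
cleared over a few hundred ms. The model treats simulated [DA]_o as the
causal convolution of the (suppression-scaled) dopamine-neuron drive with a
single-pulse release-uptake kernel K(t). K can be parametric (difference of
exponentials, default a pure 300 ms decaying exponential) or loaded from a
digitized single-pulse transient. Kernels are peak-normalized, so [DA]_o is
reported in dimensionless kernel-peak-referenced units; no micromolar
calibration is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import RateTrace

__all__ = [
    "ReleaseKernel",
    "make_parametric_kernel",
    "load_empirical_kernel",
    "read_kernel_table",
    "write_kernel_table",
    "convolve_release",
]

DEFAULT_TAU_RISE_MS = 0.0
DEFAULT_TAU_DECAY_MS = 300.0
DEFAULT_T_MAX_MS = 2000.0


@dataclass(frozen=True)
class ReleaseKernel:
    """Sampled single-pulse [DA]_o impulse response, peak-normalized to 1."""

    samples: np.ndarray
    dt: float
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        s = self.samples
        if s.ndim != 1 or s.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(s)) or np.any(s < 0):
            raise ValueError("samples must be finite and >= 0")

    @property
    def peak_lag(self) -> float:
        """Lag of the kernel maximum, in ms."""
        return float(np.argmax(self.samples) * self.dt)

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt


def make_parametric_kernel(
    tau_rise: float = DEFAULT_TAU_RISE_MS,
    tau_decay: float = DEFAULT_TAU_DECAY_MS,
    dt: float = 1.0,
    t_max: float = DEFAULT_T_MAX_MS,
) -> ReleaseKernel:
    """Difference-of-exponentials kernel, peak-normalized.

    ``tau_rise = 0`` gives a pure decaying exponential with an instantaneous
    rise. Time constants in ms; requires 0 <= tau_rise < tau_decay.
    """
    if tau_rise < 0 or tau_decay <= tau_rise:
        raise ValueError("need 0 <= tau_rise < tau_decay")
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be positive")
    t = np.arange(0.0, t_max + dt / 2, dt)
    if tau_rise == 0:
        k = np.exp(-t / tau_decay)
    else:
        k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    k = k / k.max()
    return ReleaseKernel(
        samples=k,
        dt=float(dt),
        description=f"parametric: tau_rise={tau_rise} ms, tau_decay={tau_decay} ms",
    )


def load_empirical_kernel(lags, values, dt: float) -> ReleaseKernel:
    """Build a kernel from (lag, value) records, e.g. a digitized transient.

    Lags must start at 0; non-uniform grids are resampled to ``dt`` by
    linear interpolation, and values are rescaled to peak 1.
    """
    lags = np.asarray(lags, dtype=float)
    values = np.asarray(values, dtype=float)
    if lags.size == 0 or values.size == 0:
        raise ValueError("empty kernel table")
    if lags.shape != values.shape:
        raise ValueError("lags and values must have equal length")
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValueError("kernel values must be finite and >= 0")
    if abs(lags[0]) > 1e-9:
        raise ValueError("lags must start at 0")
    if lags.size > 1 and np.any(np.diff(lags) <= 0):
        raise ValueError("lags must be strictly increasing")
    if dt <= 0:
        raise ValueError("dt must be positive")
    grid = np.arange(0.0, lags[-1] + dt / 2, dt) if lags.size > 1 else np.array([0.0])
    resampled = np.interp(grid, lags, values)
    peak = resampled.max()
    if peak <= 0:
        raise ValueError("kernel must have a positive peak")
    return ReleaseKernel(samples=resampled / peak, dt=float(dt), description="empirical")


def read_kernel_table(path, dt: float) -> ReleaseKernel:
    """Read a two-column (lag_ms, value) delimited text file as a kernel."""
    df = pd.read_csv(path, sep=None, engine="python")
    return load_empirical_kernel(
        df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float), dt
    )


def write_kernel_table(path, kernel: ReleaseKernel) -> None:
    pd.DataFrame({"lag_ms": kernel.lags, "value": kernel.samples}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def convolve_release(drive: RateTrace, kernel: ReleaseKernel) -> RateTrace:
    """Causal discrete convolution of a drive trace with the release kernel.

    out[t] = sum_tau drive[t - tau] * K[tau] * dt, truncated to the drive
    length. Output units are normalized [DA]_o (kernel-peak-referenced).
    """
    if abs(drive.dt - kernel.dt) > 1e-9:
        raise ValueError(
            f"drive dt ({drive.dt} ms) and kernel dt ({kernel.dt} ms) must match"
        )
    full = np.convolve(drive.values, kernel.samples)[: len(drive)]
    return RateTrace(drive.dt, full * drive.dt, label=f"[DA]_o({drive.label})")
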