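"""The model core: ChI activity -> suppression state -> simulated [DA]_o.

State variables, all on the simulation grid (dt in ms):

* ``u(t) = chi(t) / tonic_chi_rate`` — ChI firing normalized to its own
  tonic rate, so tonic firing is u = 1 and a pause is u -> 0.
* availability ``a(t)`` — fraction of nAChRs in an activatable state.
  Supra-tonic ChI excursions drive apparent desensitization through the
  area-normalized desensitization-level kernel:
  ``a = 1 - clamp(gamma * conv(max(u - 1, 0), d_hat) * dt, 0, 1)``.
* suppression ``S(t)`` — ChI-dependent depression of release, the sum of a
  tonic background ``beta * D_max`` and the kernel-weighted deviation of
  ChI firing from tonic:
  ``S = clamp(beta * D_max + D_max * conv(e, w_hat) * dt, 0, D_max)`` with
  ``e = max(u - 1, 0) * a + min(u - 1, 0)``. Availability gates only the
  depression-*adding* (supra-tonic) contributions — desensitized receptors
  cannot transduce new ACh — while relief by pauses is ungated because
  existing depression decays regardless of receptor state.
* release multiplier ``m(t) = 1 - S(t)``; simulated
  ``[DA]_o = conv(da(t) * m(t), K)`` with K the release-uptake kernel.

With tonic ChI firing the deviation term vanishes and S sits exactly at the
configured background ``beta * D_max``; the simulator itself is fully
deterministic (randomness lives only in synthetic input generation).

The desensitization gain ``gamma`` defaults to a value calibrated against
the multiphasic response itself: the default initial excitation (x3 tonic
for 50 ms) leaves availability at ~0.5 when the rebound begins 200 ms
later. This makes the apparent-desensitization component real but minor —
it partially gates the rebound after an excitation (more so in DLS than
NAcc) without cancelling the excitation's own contribution — while tonic
firing alone never accumulates desensitization (in vivo, nAChR antagonists
still raise dopamine during tonic activity, so tonic drive must leave
nAChRs effective).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .kernels import (
    RegionParams,
    build_region_params,
    eval_depression_strength,
    eval_desensitization_level,
    sample_kernel,
)
from .release import ReleaseKernel, convolve_release, make_parametric_kernel
from .synth import MultiphasicPattern, make_da_burst, make_multiphasic_chi, make_tonic_rate
from .traces import RateTrace

__all__ = [
    "SimConfig",
    "SimResult",
    "default_desensitization_gain",
    "compute_suppression_trace",
    "simulate_dao",
    "scenario_sweep",
    "excitation_ratio",
    "kinetics_report",
    "KineticsReport",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    beta:
        Tonic background suppression as a fraction in [0, 1] of the
        region's maximal depression strength (the canonical 0 / 50 /
        100 % levels are beta = 0, 0.5, 1).
    desensitization_gain:
        gamma (dimensionless, >= 0); None selects the calibrated regional
        default (see module docstring).
    desensitization_enabled:
        Ablation switch; False forces availability a = 1 everywhere.
    da_tonic_rate:
        If set, the dopamine drive is normalized by this tonic rate (Hz)
        before convolution, mirroring rate normalization to each
        population's own tonic frequency; None uses the drive as-is.
    analysis_window:
        (start_ms, stop_ms) over which peak / AUC / time-to-peak are
        measured; None means the full trace.
    """

    beta: float = 0.5
    desensitization_gain: float | None = None
    desensitization_enabled: bool = True
    dt: float = defaults.DT_MS
    duration: float = defaults.DURATION_MS
    kernel: ReleaseKernel | None = None
    da_tonic_rate: float | None = None
    analysis_window: tuple | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if self.desensitization_gain is not None and self.desensitization_gain < 0:
            raise ValueError("desensitization_gain must be >= 0")
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("need dt > 0 and duration >= dt")

    def release_kernel(self) -> ReleaseKernel:
        if self.kernel is not None:
            if abs(self.kernel.dt - self.dt) > 1e-9:
                raise ValueError("config.kernel dt must match config.dt")
            return self.kernel
        return make_parametric_kernel(
            defaults.TAU_RISE_MS, defaults.TAU_DECAY_MS, self.dt, defaults.KERNEL_T_MAX_MS
        )


@dataclass(frozen=True)
class SimResult:
    """Simulated [DA]_o trace plus internal state and summary statistics."""

    dao: RateTrace
    suppression: RateTrace
    availability: RateTrace
    multiplier: RateTrace
    peak: float
    auc: float
    time_to_peak: float
    analysis_window: tuple

    def to_frame(self) -> pd.DataFrame:
        """All traces as one table (time_ms + one column per trace)."""
        return pd.DataFrame(
            {
                "time_ms": self.dao.times,
                "dao": self.dao.values,
                "suppression": self.suppression.values,
                "availability": self.availability.values,
                "multiplier": self.multiplier.values,
            }
        )

    def summary(self) -> dict:
        return {
            "peak": self.peak,
            "auc": self.auc,
            "time_to_peak_ms": self.time_to_peak,
            "analysis_window_ms": list(self.analysis_window),
        }


def default_desensitization_gain(params: RegionParams, dt: float = defaults.DT_MS) -> float:
    """gamma at which the default excitation halves availability at rebound onset.

    The desensitization load at the rebound epoch (a lag of
    ``REBOUND[1]`` ms after excitation onset) produced by the default
    initial excitation (supra-tonic drive ``EXCITATION[0] - 1`` over
    ``EXCITATION[1]`` ms) is ``gamma * du * integral d_hat`` over the
    corresponding lag window; gamma is set so that load equals
    ``1 - REBOUND_AVAILABILITY_TARGET``, per region.
    """
    hi = params.desensitization_curve.valid_range[1]
    d_hat = sample_kernel(
        lambda lag: eval_desensitization_level(params, lag), dt, hi, normalization="area"
    )
    du_exc = defaults.EXCITATION[0] - 1.0
    lag_hi = defaults.REBOUND[1]
    lag_lo = lag_hi - defaults.EXCITATION[1]
    mask = (d_hat.lags >= lag_lo) & (d_hat.lags < lag_hi)
    frac = float(d_hat.values[mask].sum() * dt)
    return (1.0 - defaults.REBOUND_AVAILABILITY_TARGET) / (du_exc * frac)


def _area_normalized_kernels(params: RegionParams, dt: float):
    support = params.depression_support
    w_hat = sample_kernel(
        lambda lag: eval_depression_strength(params, lag), dt, support, normalization="area"
    )
    hi = params.desensitization_curve.valid_range[1]
    d_hat = sample_kernel(
        lambda lag: eval_desensitization_level(params, lag), dt, hi, normalization="area"
    )
    return w_hat, d_hat


def _causal_conv(signal: np.ndarray, kernel: np.ndarray, dt: float) -> np.ndarray:
    return np.convolve(signal, kernel)[: signal.size] * dt


def compute_suppression_trace(
    chi: RateTrace, params: RegionParams, config: SimConfig
) -> tuple[RateTrace, RateTrace]:
    """ChI rate trace -> (suppression S, availability a), both on chi's grid."""
    if abs(chi.dt - config.dt) > 1e-9:
        raise ValueError(f"chi.dt ({chi.dt}) must equal config.dt ({config.dt})")
    if np.any(chi.values < 0):
        raise ValueError("ChI rates must be >= 0")
    dt = config.dt
    u = chi.values / params.tonic_chi_rate
    du = u - 1.0
    pos = np.maximum(du, 0.0)
    neg = np.minimum(du, 0.0)

    w_hat, d_hat = _area_normalized_kernels(params, dt)

    if config.desensitization_enabled:
        gamma = (
            config.desensitization_gain
            if config.desensitization_gain is not None
            else default_desensitization_gain(params, dt)
        )
        load = gamma * _causal_conv(pos, d_hat.values, dt)
        a = 1.0 - np.clip(load, 0.0, 1.0)
    else:
        a = np.ones_like(u)

    d_max = params.depression_max
    drive = pos * a + neg
    s = np.clip(d_max * (config.beta + _causal_conv(drive, w_hat.values, dt)), 0.0, d_max)
    return (
        RateTrace(dt, s, label=f"suppression({params.region.value})"),
        RateTrace(dt, a, label=f"availability({params.region.value})"),
    )


def _window_slice(trace: RateTrace, window: tuple | None) -> tuple[slice, tuple]:
    if window is None:
        return slice(0, len(trace)), (0.0, trace.duration)
    lo, hi = window
    if not 0 <= lo < hi <= trace.duration + trace.dt / 2:
        raise ValueError(f"analysis window {window} outside trace [0, {trace.duration}]")
    i0 = int(round(lo / trace.dt))
    i1 = int(round(hi / trace.dt))
    return slice(i0, max(i1, i0 + 1)), (lo, hi)


def simulate_dao(
    da: RateTrace,
    chi: RateTrace | None,
    params: RegionParams,
    config: SimConfig,
) -> SimResult:
    """Simulate normalized extracellular dopamine for paired DA/ChI drives.

    ``chi=None`` means no ChI modulation at all (multiplier identically 1,
    regardless of beta) — the no-ChI reference used for normalization.
    """
    if chi is not None and (abs(da.dt - chi.dt) > 1e-9 or len(da) != len(chi)):
        raise ValueError("da and chi must share dt and length")
    if abs(da.dt - config.dt) > 1e-9:
        raise ValueError(f"da.dt ({da.dt}) must equal config.dt ({config.dt})")

    if chi is None:
        n = len(da)
        s_trace = RateTrace(da.dt, np.zeros(n), label="suppression(none)")
        a_trace = RateTrace(da.dt, np.ones(n), label="availability(none)")
    else:
        s_trace, a_trace = compute_suppression_trace(chi, params, config)
    m = 1.0 - s_trace.values

    drive = da.values * m
    if config.da_tonic_rate is not None:
        if config.da_tonic_rate <= 0:
            raise ValueError("da_tonic_rate must be > 0")
        drive = drive / config.da_tonic_rate
    dao = convolve_release(
        RateTrace(da.dt, drive, label=da.label), config.release_kernel()
    )

    sl, window = _window_slice(dao, config.analysis_window)
    seg = dao.values[sl]
    peak_idx = int(np.argmax(seg))
    return SimResult(
        dao=dao,
        suppression=s_trace,
        availability=a_trace,
        multiplier=RateTrace(da.dt, m, label="release multiplier"),
        peak=float(seg[peak_idx]),
        auc=float(seg.sum() * da.dt),
        time_to_peak=float(peak_idx * da.dt),
        analysis_window=window,
    )


# ---------------------------------------------------------------------------
# Scenario plumbing


def _default_pattern(tonic_rate: float) -> MultiphasicPattern:
    return MultiphasicPattern(
        tonic_rate=tonic_rate,
        excitation=defaults.EXCITATION,
        pause=defaults.PAUSE,
        rebound=defaults.REBOUND,
    )


def resolve_chi_pattern(
    label: str,
    duration: float,
    dt: float,
    tonic_rate: float = defaults.CHI_TONIC_HZ,
    onset: float = defaults.PATTERN_ONSET_MS,
) -> RateTrace | None:
    """Build a ChI rate trace from a registered pattern label.

    Labels: "tonic", "multiphasic_with_excitation",
    "multiphasic_no_excitation", "pause" (pause only, no excitation or
    rebound) and "none" (no ChI modulation; returns None).
    """
    if label == "none":
        return None
    if label == "tonic":
        return make_tonic_rate(tonic_rate, duration, dt)
    if label == "multiphasic_with_excitation":
        pattern = _default_pattern(tonic_rate)
    elif label == "multiphasic_no_excitation":
        pattern = _default_pattern(tonic_rate).without_excitation()
    elif label == "pause":
        # Rebound multiplier 1 makes the rebound window indistinguishable
        # from tonic firing; only the pause remains.
        pattern = MultiphasicPattern(
            tonic_rate=tonic_rate,
            excitation=None,
            pause=defaults.PAUSE,
            rebound=(1.0, defaults.REBOUND[1], defaults.REBOUND[2]),
        )
    else:
        raise ValueError(
            f"unknown ChI pattern {label!r}; known: tonic, "
            "multiphasic_with_excitation, multiphasic_no_excitation, pause, none"
        )
    return make_multiphasic_chi(pattern, duration, dt, onset=onset)


def resolve_da_pattern(
    label: str,
    duration: float,
    dt: float,
    tonic_rate: float = defaults.DA_TONIC_HZ,
    onset: float = defaults.PATTERN_ONSET_MS,
) -> RateTrace:
    """Build a DA rate trace from a label: "tonic", "burst" or "impulse"."""
    if label == "tonic":
        return make_tonic_rate(tonic_rate, duration, dt)
    if label == "burst":
        return make_da_burst(
            tonic_rate,
            tonic_rate * defaults.DA_BURST_MULT,
            onset + defaults.DA_BURST_OFFSET_MS,
            defaults.DA_BURST_DURATION_MS,
            duration,
            dt,
        )
    if label == "impulse":
        trace = make_tonic_rate(0.0, duration, dt)
        values = trace.values.copy()
        values[int(round(onset / dt))] = 1.0 / dt
        return RateTrace(dt, values, label="DA impulse")
    raise ValueError(f"unknown DA pattern {label!r}; known: tonic, burst, impulse")


def scenario_sweep(
    scenarios: Iterable[tuple],
    params: RegionParams | Sequence[RegionParams],
    config: SimConfig,
) -> pd.DataFrame:
    """Run (da pattern, chi pattern, beta) scenarios; one summary row each.

    Patterns may be labels (resolved via :func:`resolve_da_pattern` /
    :func:`resolve_chi_pattern`) or ready-made :class:`RateTrace` objects.
    ``params`` may be a single region or a sequence of regions to cross
    with every scenario.
    """
    regions = [params] if isinstance(params, RegionParams) else list(params)
    rows = []
    for da_spec, chi_spec, beta in scenarios:
        for region_params in regions:
            cfg = replace(config, beta=float(beta))
            da = (
                da_spec
                if isinstance(da_spec, RateTrace)
                else resolve_da_pattern(da_spec, cfg.duration, cfg.dt)
            )
            chi = (
                chi_spec
                if isinstance(chi_spec, RateTrace) or chi_spec is None
                else resolve_chi_pattern(
                    chi_spec, cfg.duration, cfg.dt, region_params.tonic_chi_rate
                )
            )
            result = simulate_dao(da, chi, region_params, cfg)
            rows.append(
                {
                    "region": region_params.region.value,
                    "beta": float(beta),
                    "da_pattern": da_spec if isinstance(da_spec, str) else da.label,
                    "chi_pattern": (
                        chi_spec
                        if isinstance(chi_spec, str)
                        else ("none" if chi is None else chi.label)
                    ),
                    "peak": result.peak,
                    "auc": result.auc,
                    "time_to_peak_ms": result.time_to_peak,
                }
            )
    return pd.DataFrame(rows)


def excitation_ratio(no_excitation: SimResult, with_excitation: SimResult):
    """(peak ratio, AUC ratio) of the without- over the with-excitation run."""
    if with_excitation.peak == 0 or with_excitation.auc == 0:
        raise ZeroDivisionError(
            "with-excitation result has zero peak or AUC; ratio undefined "
            f"(peak={with_excitation.peak}, auc={with_excitation.auc})"
        )
    return (
        no_excitation.peak / with_excitation.peak,
        no_excitation.auc / with_excitation.auc,
    )


@dataclass(frozen=True)
class KineticsReport:
    """Shape comparison of two [DA]_o traces after peak normalization."""

    time_to_peak_diff: float
    max_shape_diff: float


def kinetics_report(result: SimResult, reference: SimResult) -> KineticsReport:
    """Compare [DA]_o kinetics: time-to-peak shift and peak-normalized shape.

    Constant suppression rescales [DA]_o without changing its time course,
    so the shape difference is ~0; time-varying suppression during release
    produces a genuine shape difference.
    """
    if abs(result.dao.dt - reference.dao.dt) > 1e-9 or len(result.dao) != len(reference.dao):
        raise ValueError("results must share the simulation grid")
    if result.peak == 0 or reference.peak == 0:
        raise ZeroDivisionError("cannot peak-normalize a zero-peak trace")
    shape_diff = np.max(
        np.abs(result.dao.values / result.peak - reference.dao.values / reference.peak)
    )
    return KineticsReport(
        time_to_peak_diff=float(result.time_to_peak - reference.time_to_peak),
        max_shape_diff=float(shape_diff),
    )
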