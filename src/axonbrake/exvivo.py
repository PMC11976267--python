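"""Ex vivo paired-pulse analysis: composite subtraction and ratio curves.

The measurement procedure mirrors the slice experiments the kernels came
from: a conditioning stimulus (activating ChIs/nAChRs) is followed ``isi``
ms later by a test stimulus of the dopamine axons; the [DA]_o transient
attributable to the test stimulus is isolated by subtracting the
conditioning-alone transient from the composite, and its peak is normalized
to a lone single-stimulus response. Comparing the normalized test release
with nAChRs intact versus antagonized isolates the cholinergic brake:
the on/off ratio equals 1 - D(isi), with D the region's depression-strength
kernel.

This module is a consistency surface, not an independent re-derivation:
the kernels were fit by others from data that are not tabulated, so the
pipeline demonstrates that the implemented model, pushed through the
measurement procedure it was built from, returns the curves it encodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernels import RegionParams, eval_depression_strength
from .release import ReleaseKernel, make_parametric_kernel
from .traces import RateTrace

__all__ = ["PairedPulseOutcome", "subtract_composite", "normalized_second_pulse", "depression_curve"]


@dataclass(frozen=True)
class PairedPulseOutcome:
    """Normalized release values for one ex vivo paired-pulse condition."""

    isi: float
    region: str
    nachr_on: bool
    release_1: float
    release_2: float
    ratio: float | None = None  # release_2(on) / release_2(off), if paired

    def __post_init__(self) -> None:
        if self.release_1 < 0 or self.release_2 < 0:
            raise ValueError("release values must be >= 0")


def subtract_composite(
    composite: RateTrace, single_first: RateTrace, isi: float
) -> RateTrace:
    """Isolate the second-stimulus transient from a composite response.

    Bin-wise ``composite - single_first`` floored at 0, with both traces
    aligned to the first stimulus on a shared grid. ``isi`` is carried as
    metadata in the label.
    """
    if abs(composite.dt - single_first.dt) > 1e-9 or len(composite) != len(single_first):
        raise ValueError("composite and single-stimulus traces must share the grid")
    diff = np.maximum(composite.values - single_first.values, 0.0)
    return RateTrace(composite.dt, diff, label=f"second-stimulus transient (isi={isi} ms)")


def _place_transient(n: int, dt: float, onset: float, amplitude: float, kernel: ReleaseKernel) -> np.ndarray:
    out = np.zeros(n)
    i0 = int(round(onset / dt))
    span = min(kernel.samples.size, n - i0)
    out[i0 : i0 + span] = amplitude * kernel.samples[:span]
    return out


def normalized_second_pulse(
    params: RegionParams,
    isi: float,
    nachr_on: bool,
    kernel: ReleaseKernel | None = None,
    dt: float = 1.0,
) -> PairedPulseOutcome:
    """Simulated paired-pulse outcome at one ISI.

    The conditioning event installs depression D(isi) on the test release
    when nAChRs are on, and none when they are antagonized (the model
    excludes nAChR-independent short-term depression). The composite
    transient is then decomposed by :func:`subtract_composite` and the
    isolated test peak is normalized to a lone single-stimulus response,
    detected as the maximum within one depression-support length of the
    stimulus (earliest bin on ties).
    """
    lo, hi = params.depression_curve.valid_range
    if not lo <= isi <= hi:
        raise ValueError(f"isi {isi} ms outside the kernel valid range [{lo}, {hi}] ms")
    if kernel is None:
        kernel = make_parametric_kernel(dt=dt)
    dt = kernel.dt
    n = int(round(isi / dt)) + kernel.samples.size + 10

    depression = eval_depression_strength(params, isi) if nachr_on else 0.0
    amp_2 = 1.0 - depression

    single_first = RateTrace(dt, _place_transient(n, dt, 0.0, 1.0, kernel))
    composite = RateTrace(
        dt, single_first.values + _place_transient(n, dt, isi, amp_2, kernel)
    )
    isolated = subtract_composite(composite, single_first, isi)

    # Lone single-stimulus reference for normalization.
    reference = _place_transient(n, dt, 0.0, 1.0, kernel)
    ref_peak = reference.max()

    i_test = int(round(isi / dt))
    i_stop = min(n, i_test + int(round(params.depression_support / dt)) + 1)
    release_2 = float(isolated.values[i_test:i_stop].max() / ref_peak)
    return PairedPulseOutcome(
        isi=float(isi),
        region=params.region.value,
        nachr_on=nachr_on,
        release_1=1.0,
        release_2=release_2,
    )


def depression_curve(
    params: RegionParams,
    isis,
    kernel: ReleaseKernel | None = None,
    dt: float = 1.0,
) -> pd.DataFrame:
    """Paired-pulse outcomes for both nAChR states across ISIs.

    Returns one row per (isi, nachr_on) with columns region, isi_ms,
    nachr_on, release_1, release_2 and ratio (on/off at the same ISI).
    """
    rows = []
    for isi in isis:
        if isi < 0:
            raise ValueError("isis must be >= 0")
        on = normalized_second_pulse(params, isi, True, kernel=kernel, dt=dt)
        off = normalized_second_pulse(params, isi, False, kernel=kernel, dt=dt)
        ratio = on.release_2 / off.release_2 if off.release_2 > 0 else np.nan
        for outcome in (on, off):
            rows.append(
                {
                    "region": outcome.region,
                    "isi_ms": outcome.isi,
                    "nachr_on": outcome.nachr_on,
                    "release_1": outcome.release_1,
                    "release_2": outcome.release_2,
                    "ratio": ratio,
                }
            )
    return pd.DataFrame(rows)
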