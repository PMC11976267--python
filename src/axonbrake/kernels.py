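"""Region-specific kernels of the cholinergic brake on dopamine release.

Two empirical curves per striatal region (dorsolateral striatum, DLS, and
nucleus accumbens core, NAcc) drive the model:

* the **depression strength** ``D(lag)`` — the fraction of dopamine release
  suppressed ``lag`` ms after cholinergic-interneuron (ChI)/nAChR
  activation, measured ex vivo as the paired-pulse deficit that is relieved
  by a beta2-nAChR antagonist, and summarized as a quadratic in the
  interstimulus lag (ms);
* the **apparent desensitization level** ``d(lag)`` — the normalized
  inability of nAChRs to be re-activated ``lag`` ms after activation,
  summarized as a quadratic (DLS) or quartic (NAcc) in lag.

Conventions
-----------
The two regional desensitization fits are printed in opposite conventions:
the DLS quadratic describes remaining *nAChR control* (a U with its minimum
near 217 ms), whereas the NAcc quartic describes the *desensitization level*
itself (a peak near 115 ms). Both are mapped internally onto a single
desensitization-level convention: the DLS curve is stored with
``convention="complement"`` (level = 1 - curve) and the NAcc curve with
``convention="level"``. The raw-level maxima then fall at ~200 ms (DLS) and
~100 ms (NAcc), matching the measured triplet-minus-single release
difference.

Units and clamping
------------------
``lag`` is in ms throughout. The depression quadratics are evaluated with
their quadratic coefficients at the 1e-5 scale, which places their first
positive roots near 190 ms (DLS) and 68 ms (NAcc) — the observed suppression
windows. Clamped evaluations confine both kernels to [0, 1]; the depression
kernel has compact support ending at its smallest positive root (half-open:
a lag exactly at the root evaluates to 0), and beyond the 400 ms trusted
range the desensitization level is taken as 0 (receptors fully recovered).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from numpy.polynomial import polynomial as P

__all__ = [
    "Region",
    "PolynomialCurve",
    "RegionParams",
    "build_region_params",
    "eval_depression_strength",
    "eval_desensitization_level",
    "eval_activatable_fraction",
    "sample_kernel",
    "SampledKernel",
]

#: Largest interstimulus lag (ms) probed experimentally; fits are not
#: trusted beyond it.
VALID_RANGE_MS = (0.0, 400.0)


class Region(str, enum.Enum):
    """Modeled striatal region."""

    DLS = "DLS"
    NACC = "NAcc"

    @classmethod
    def coerce(cls, value) -> "Region":
        if isinstance(value, cls):
            return value
        for member in cls:
            if str(value).lower() == member.value.lower():
                return member
        accepted = ", ".join(m.value for m in cls)
        raise ValueError(f"unknown region {value!r}; accepted values: {accepted}")


@dataclass(frozen=True)
class PolynomialCurve:
    """A fitted polynomial y(x) with x in ms, coefficients in ascending degree.

    ``r_squared`` is fit-quality metadata from the original regression and is
    never recomputed here (the underlying raw points are not available).
    """

    coefficients: tuple
    valid_range: tuple = VALID_RANGE_MS
    r_squared: float | None = None

    def __post_init__(self) -> None:
        coefs = tuple(float(c) for c in self.coefficients)
        if not coefs or not all(np.isfinite(coefs)):
            raise ValueError("coefficients must be non-empty and finite")
        lo, hi = self.valid_range
        if lo < 0 or hi > VALID_RANGE_MS[1] or hi <= lo:
            raise ValueError(f"valid_range must lie within {VALID_RANGE_MS}")
        object.__setattr__(self, "coefficients", coefs)

    def __call__(self, x):
        return P.polyval(np.asarray(x, dtype=float), self.coefficients)

    def smallest_positive_root(self) -> float | None:
        """Smallest real root > 0, or None if the curve never crosses zero."""
        roots = np.polynomial.Polynomial(self.coefficients).roots()
        real = roots[np.abs(roots.imag) < 1e-9].real
        positive = real[real > 1e-12]
        return float(positive.min()) if positive.size else None


@dataclass(frozen=True)
class RegionParams:
    """Default kernel parameters for one striatal region.

    ``desensitization_convention`` records whether the stored curve is the
    desensitization level itself ("level") or its complement, remaining
    nAChR control ("complement").
    """

    region: Region
    depression_curve: PolynomialCurve
    desensitization_curve: PolynomialCurve
    desensitization_convention: str
    tonic_chi_rate: float = 5.0  # Hz; ChIs fire tonically at 3-10 Hz

    def __post_init__(self) -> None:
        if self.desensitization_convention not in ("level", "complement"):
            raise ValueError("desensitization_convention must be 'level' or 'complement'")
        if not 3.0 <= self.tonic_chi_rate <= 10.0:
            raise ValueError("tonic_chi_rate should lie in the physiological 3-10 Hz band")

    @property
    def depression_max(self) -> float:
        """Maximal depression strength: the clamped depression value at lag 0."""
        return float(np.clip(self.depression_curve(0.0), 0.0, 1.0))

    @property
    def depression_support(self) -> float:
        """End of the depression kernel's compact support (ms)."""
        root = self.depression_curve.smallest_positive_root()
        return float(root) if root is not None else self.depression_curve.valid_range[1]


# Printed regression summaries; quadratic depression coefficients at the
# 1e-5 scale (see module docstring), lag in ms, ascending degree order.
_DEFAULTS = {
    Region.DLS: dict(
        depression=PolynomialCurve((0.872, -0.00833, 1.97e-5), r_squared=0.99),
        desensitization=PolynomialCurve((0.88, -0.0087, 2e-5)),
        convention="complement",
    ),
    Region.NACC: dict(
        depression=PolynomialCurve((0.611, -0.0149, 8.71e-5), r_squared=0.96),
        desensitization=PolynomialCurve((-0.5654, 0.039, -0.0003, 9e-7, -9e-10)),
        convention="level",
    ),
}


def build_region_params(region) -> RegionParams:
    """Return the default :class:`RegionParams` for ``region`` (DLS or NAcc)."""
    region = Region.coerce(region)
    entry = _DEFAULTS[region]
    return RegionParams(
        region=region,
        depression_curve=entry["depression"],
        desensitization_curve=entry["desensitization"],
        desensitization_convention=entry["convention"],
    )


def _check_lag(lag) -> np.ndarray:
    lag = np.asarray(lag, dtype=float)
    if np.any(lag < 0):
        raise ValueError("lag must be >= 0 ms")
    return lag


def eval_depression_strength(params: RegionParams, lag, *, clamp: bool = True):
    """Depression strength D at ``lag`` ms after ChI/nAChR activation.

    With ``clamp`` (default) the raw polynomial is clipped to [0, 1] and set
    to 0 for every lag at or beyond its smallest positive root: the kernel
    has compact support and the unphysical re-growth of the quadratic past
    its second root is discarded. ``clamp=False`` returns the raw fit.
    """
    lag = _check_lag(lag)
    raw = params.depression_curve(lag)
    if not clamp:
        return raw if raw.ndim else float(raw)
    out = np.clip(raw, 0.0, 1.0)
    out = np.where(lag >= params.depression_support, 0.0, out)
    return out if out.ndim else float(out)


def eval_desensitization_level(params: RegionParams, lag, *, clamp: bool = True):
    """Apparent desensitization level d at ``lag`` ms after activation.

    The stored curve is harmonized to the level convention first
    (``level = 1 - curve`` when the curve is stored as the complement).
    Clamping clips to [0, 1] and declares full recovery (level 0) beyond the
    trusted 400 ms range, where the NAcc quartic grows unphysically.
    """
    lag = _check_lag(lag)
    raw = params.desensitization_curve(lag)
    if params.desensitization_convention == "complement":
        raw = 1.0 - raw
    if not clamp:
        return raw if raw.ndim else float(raw)
    out = np.clip(raw, 0.0, 1.0)
    out = np.where(lag > params.desensitization_curve.valid_range[1], 0.0, out)
    return out if out.ndim else float(out)


def eval_activatable_fraction(params: RegionParams, lag):
    """Fraction of nAChRs in an activatable state: a = 1 - clamp(d)."""
    return 1.0 - eval_desensitization_level(params, lag, clamp=True)


class SampledKernel(NamedTuple):
    """A kernel evaluated on a uniform lag grid."""

    lags: np.ndarray
    values: np.ndarray
    dt: float


def sample_kernel(
    func: Callable,
    dt: float,
    t_max: float,
    normalization: str = "none",
) -> SampledKernel:
    """Sample ``func(lag)`` on a uniform grid [0, t_max] with step dt.

    normalization: "none", "peak" (divide by the maximum sample) or "area"
    (divide by sum * dt so the sampled kernel integrates to 1).
    """
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be positive")
    lags = np.arange(0.0, t_max + dt / 2, dt)
    values = np.asarray(func(lags), dtype=float)
    if normalization == "peak":
        peak = values.max()
        if peak <= 0:
            raise ValueError("cannot peak-normalize a non-positive kernel")
        values = values / peak
    elif normalization == "area":
        area = values.sum() * dt
        if area <= 0:
            raise ValueError("cannot area-normalize a zero-area kernel")
        values = values / area
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    return SampledKernel(lags=lags, values=values, dt=float(dt))
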