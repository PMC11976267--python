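"""Synthetic firing-rate patterns and stimulation protocols.

Generates every input the simulator consumes:

* tonic ChI firing (3-10 Hz band, default 5 Hz), optionally jittered;
* the in vivo multiphasic ChI response — an optional initial excitation,
  a pause, and a rebound ~100-300 ms after excitation onset;
* dopamine-neuron tonic firing plus a rectangular phasic burst;
* ex vivo paired-pulse protocols (conditioning + test events at one ISI);
* optional inhomogeneous-Poisson spike realizations of any rate trace.

Phase envelopes are deliberately rectangular: output kinetics in this model
come from the kernels, not from the input envelopes. The default amplitudes
and durations are stand-ins chosen within the published constraints (the
exact in vivo patterns behind the burst/pause/rebound scenarios are not
tabulated); all of them are exposed through :mod:`axonbrake.defaults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import EventTrain, RateTrace

__all__ = [
    "MultiphasicPattern",
    "make_tonic_rate",
    "make_multiphasic_chi",
    "make_da_burst",
    "make_paired_pulse_protocol",
    "poissonify",
]


@dataclass(frozen=True)
class MultiphasicPattern:
    """Burst-pause-rebound ChI response specification.

    excitation: (rate multiplier, duration ms) or None to omit the initial
        excitation while keeping the pause/rebound timing fixed (half of
        ChIs respond without the initial excitation).
    pause: (depth fraction in [0, 1], duration ms); depth 1 silences firing.
        The pause starts when the excitation window ends.
    rebound: (rate multiplier, onset ms after excitation onset, duration ms).
    """

    tonic_rate: float = 5.0
    excitation: tuple | None = (3.0, 50.0)
    pause: tuple = (1.0, 150.0)
    rebound: tuple = (2.0, 200.0, 100.0)
    excitation_duration_if_absent: float = 50.0

    def __post_init__(self) -> None:
        if self.tonic_rate < 0:
            raise ValueError("tonic_rate must be >= 0")
        depth, pause_dur = self.pause
        if not 0.0 <= depth <= 1.0:
            raise ValueError("pause depth must be in [0, 1]")
        exc_dur = self.excitation[1] if self.excitation else self.excitation_duration_if_absent
        reb_mult, reb_onset, reb_dur = self.rebound
        if min(exc_dur, pause_dur, reb_dur) <= 0:
            raise ValueError("all phase durations must be > 0")
        if self.excitation and self.excitation[0] < 0:
            raise ValueError("excitation multiplier must be >= 0")
        if reb_onset < exc_dur + pause_dur:
            raise ValueError(
                "rebound overlaps earlier phases: onset "
                f"{reb_onset} ms < excitation+pause {exc_dur + pause_dur} ms"
            )

    @property
    def excitation_window(self) -> tuple:
        dur = self.excitation[1] if self.excitation else self.excitation_duration_if_absent
        return (0.0, dur)

    @property
    def span(self) -> float:
        """Total extent of the pattern from excitation onset, in ms."""
        return self.rebound[1] + self.rebound[2]

    def without_excitation(self) -> "MultiphasicPattern":
        """Same pattern with the initial excitation removed, timing kept."""
        dur = self.excitation[1] if self.excitation else self.excitation_duration_if_absent
        return MultiphasicPattern(self.tonic_rate, None, self.pause, self.rebound, dur)


def make_tonic_rate(
    rate: float,
    duration: float,
    dt: float = 1.0,
    jitter_sd: float = 0.0,
    seed: int | None = None,
    label: str = "tonic",
) -> RateTrace:
    """Constant-rate trace with optional Gaussian jitter, floored at 0 Hz."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    n = int(round(duration / dt))
    if n < 1:
        raise ValueError("duration must cover at least one bin")
    values = np.full(n, float(rate))
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        values = np.maximum(values + rng.normal(0.0, jitter_sd, size=n), 0.0)
    return RateTrace(dt, values, label=label)


def make_multiphasic_chi(
    pattern: MultiphasicPattern,
    duration: float,
    dt: float = 1.0,
    onset: float = 0.0,
) -> RateTrace:
    """Piecewise-constant multiphasic ChI trace.

    Phases run tonic -> (excitation) -> pause -> tonic gap (if any) ->
    rebound -> tonic, with ``onset`` the excitation-onset time in ms. When
    the excitation is absent its window stays tonic, so with- and without-
    excitation traces are identical outside that window.
    """
    if onset < 0:
        raise ValueError("onset must be >= 0")
    if onset + pattern.span > duration:
        raise ValueError(
            f"pattern (onset {onset} ms + span {pattern.span} ms) "
            f"does not fit within duration {duration} ms"
        )
    trace = make_tonic_rate(pattern.tonic_rate, duration, dt, label="multiphasic ChI")
    values = trace.values.copy()
    t = trace.times
    exc_lo, exc_hi = pattern.excitation_window
    if pattern.excitation is not None:
        mult, _ = pattern.excitation
        values[(t >= onset + exc_lo) & (t < onset + exc_hi)] = pattern.tonic_rate * mult
    depth, pause_dur = pattern.pause
    pause_lo = onset + exc_hi
    values[(t >= pause_lo) & (t < pause_lo + pause_dur)] = pattern.tonic_rate * (1 - depth)
    reb_mult, reb_onset, reb_dur = pattern.rebound
    values[(t >= onset + reb_onset) & (t < onset + reb_onset + reb_dur)] = (
        pattern.tonic_rate * reb_mult
    )
    label = "multiphasic ChI" + ("" if pattern.excitation else " (no excitation)")
    return RateTrace(dt, values, label=label)


def make_da_burst(
    tonic_rate: float,
    burst_rate: float,
    burst_onset: float,
    burst_duration: float,
    duration: float,
    dt: float = 1.0,
) -> RateTrace:
    """Tonic dopamine-neuron firing with a rectangular phasic burst."""
    if burst_rate < tonic_rate:
        raise ValueError("burst_rate must be >= tonic_rate")
    if burst_onset < 0 or burst_onset + burst_duration > duration:
        raise ValueError("burst must lie within the trace duration")
    trace = make_tonic_rate(tonic_rate, duration, dt, label="DA tonic+burst")
    values = trace.values.copy()
    t = trace.times
    values[(t >= burst_onset) & (t < burst_onset + burst_duration)] = float(burst_rate)
    return RateTrace(dt, values, label="DA tonic+burst")


_PROTOCOL_KINDS = ("chi_then_estim", "estim_then_da", "da_only")


def make_paired_pulse_protocol(isi: float, kind: str = "chi_then_estim"):
    """Conditioning + test event trains separated by ``isi`` ms.

    kind labels which population each event targets: "chi_then_estim"
    (ChI/nAChR conditioning then electrical test), "estim_then_da"
    (electrical conditioning then targeted DA-axon test) or "da_only"
    (no conditioning event).
    """
    if isi <= 0:
        raise ValueError("isi must be > 0 ms")
    if kind not in _PROTOCOL_KINDS:
        raise ValueError(f"kind must be one of {_PROTOCOL_KINDS}, got {kind!r}")
    if kind == "da_only":
        conditioning = EventTrain(np.array([]), kind="stimulus", label="none")
    else:
        target = "ChI" if kind == "chi_then_estim" else "Estim"
        conditioning = EventTrain(np.array([0.0]), kind="stimulus", label=target)
    test_target = "Estim" if kind == "chi_then_estim" else "DA axon"
    test = EventTrain(np.array([float(isi)]), kind="stimulus", label=test_target)
    return conditioning, test


def poissonify(trace: RateTrace, seed: int | None = None) -> EventTrain:
    """Inhomogeneous-Poisson spike realization of a rate trace (per-bin thinning).

    Each bin fires at most one spike with probability rate * dt (rate in Hz,
    dt converted from ms to s); adequate for rates well below 1/dt.
    """
    rng = np.random.default_rng(seed)
    p = trace.values * trace.dt / 1000.0
    hits = rng.random(len(trace)) < p
    times = trace.times[hits]
    return EventTrain(times, kind="spike", label=f"poisson({trace.label})")
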