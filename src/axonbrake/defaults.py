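"""Versioned default study conditions for simulations and sweeps.

Everything here is a stand-in chosen once, within published constraints,
for inputs that are not tabulated anywhere: ChI tonic firing 5 Hz (within
the 3-10 Hz band), initial excitation x3 for 50 ms, a full 150 ms pause,
a x2 rebound starting 200 ms after excitation onset (inside the observed
~100-300 ms window) for 100 ms; dopamine neurons at 4 Hz tonic with a x5
burst for 200 ms concurrent with the multiphasic response. The burst is
placed to overlap the late pause and the rebound, the epoch the in vivo
recordings emphasize for burst dopamine release. All values are plain
module constants so configuration files can override any of them.
"""

from __future__ import annotations

CHI_TONIC_HZ = 5.0
DA_TONIC_HZ = 4.0

EXCITATION = (3.0, 50.0)          # (rate multiplier, duration ms)
PAUSE = (1.0, 150.0)              # (depth fraction, duration ms)
REBOUND = (2.0, 200.0, 100.0)     # (multiplier, onset ms after excitation onset, duration ms)

#: Excitation-onset time of the multiphasic pattern (ms); leaves one full
#: desensitization-kernel length (400 ms) of burn-in before any event.
PATTERN_ONSET_MS = 600.0

#: DA burst timing relative to the pattern onset, and its shape. The burst
#: spans the excitation's suppression window, the pause and the first part
#: of the rebound, so every phase of the multiphasic response acts on some
#: portion of burst-evoked release.
DA_BURST_OFFSET_MS = 50.0
DA_BURST_DURATION_MS = 200.0
DA_BURST_MULT = 5.0

#: nAChR availability remaining at the rebound epoch after the default
#: initial excitation; anchors the desensitization gain (see
#: axonbrake.simulate.default_desensitization_gain).
REBOUND_AVAILABILITY_TARGET = 0.5

DT_MS = 1.0
DURATION_MS = 1500.0

#: Release-uptake kernel time constants (ms).
TAU_RISE_MS = 0.0
TAU_DECAY_MS = 300.0
KERNEL_T_MAX_MS = 2000.0

#: Background suppression levels explored in sweeps (fractions of the
#: region's maximal depression strength).
BETA_LEVELS = (0.0, 0.5, 1.0)

#: ISIs (ms) probed by the ex vivo paired-pulse validation.
PAIRED_PULSE_ISIS = (7.0, 25.0, 50.0, 100.0, 200.0, 400.0)


def as_dict() -> dict:
    """All defaults as a plain dict (for manifests and config echoes)."""
    return {
        k: v
        for k, v in globals().items()
        if k.isupper() and not k.startswith("_")
    }
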