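# Methods

## The model

`axonbrake` implements a deterministic firing-rate model of the "axonal
brake": striatal cholinergic interneurons (ChIs), acting through
β2-containing nicotinic acetylcholine receptors (nAChRs) on dopamine
axons, transiently prevent the re-activation of those axons by subsequent
action potentials, so dopamine output is inversely scaled by recent ChI
activity. The model is built from three empirical ingredients per striatal
region (dorsolateral striatum, DLS; nucleus accumbens core, NAcc):

1. **Depression strength** `D(Δt)` — the fraction of dopamine release
   suppressed `Δt` ms after ChI/nAChR activation, summarized by a fitted
   quadratic in the interstimulus lag:
   - DLS: `D(x) = 1.97e-5·x² − 0.00833·x + 0.872` (R² = 0.99)
   - NAcc: `D(x) = 8.71e-5·x² − 0.0149·x + 0.611` (R² = 0.96)

   The quadratic coefficients are used at the 1e-5 scale; at that scale
   the curves' first positive roots fall at 190.6 ms (DLS) and 68.2 ms
   (NAcc), exactly the observed regional suppression windows, and match
   the 1e-5 formatting of the DLS desensitization fit. R² values are
   stored as fit metadata only — the underlying raw points are not
   available, so the fits are never recomputed.

2. **Apparent desensitization** `d(Δt)` — the normalized inability of
   nAChRs to be (re)activated `Δt` ms after activation, summarized by a
   quadratic (DLS: `2e-5·x² − 0.0087·x + 0.88`) or quartic (NAcc:
   `−9e-10·x⁴ + 9e-7·x³ − 0.0003·x² + 0.039·x − 0.5654`). The two
   regional fits are printed in opposite conventions: the DLS quadratic
   describes remaining nAChR *control* (a U-shaped curve with its minimum
   at 217.5 ms), the NAcc quartic the desensitization *level* (an interior
   peak near 119 ms). They are harmonized internally to a single
   level convention by storing the DLS curve as the complement
   (`level = 1 − curve`). The raw levels then peak at ~218 ms (DLS) and
   ~119 ms (NAcc), consistent with the measured triplet-minus-single
   release differences peaking at ~200 and ~100 ms.

3. **Release–uptake kernel** `K(t)` — the extracellular dopamine
   transient after a single stimulus. No parameters for the empirical
   transient are published, so the default is parametric: a decaying
   exponential with instantaneous rise and a 300 ms decay constant,
   peak-normalized, truncated at 2 s. A difference-of-exponentials rise
   and digitized empirical transients (two-column text tables) are
   supported. All simulated `[DA]_o` is in dimensionless,
   kernel-peak-referenced units; no micromolar calibration is attempted
   because the modeled outputs are normalized.

### Clamping and conventions

Lags are in ms everywhere. Clamped kernel evaluations confine both curves
to [0, 1]. The depression kernel has compact support ending at its
smallest positive root (half-open: the root itself evaluates to 0); the
quadratic's unphysical re-growth past its second root is discarded.
Desensitization is clamped to [0, 1] within the trusted 0–400 ms range
(400 ms is the largest lag probed) and is 0 — fully recovered — beyond
it, because the NAcc quartic grows without bound past 400 ms.

### State update

On a uniform grid with step `dt` (default 1 ms), with `u(t) =
chi(t) / tonic_chi_rate` and `Δu = u − 1`:

- **Availability** `a(t) = 1 − clamp(γ · [max(Δu, 0) ∗ d̂](t) · dt, 0, 1)`,
  where `d̂` is the clamped desensitization level normalized to unit area
  and `∗` is causal convolution. Only supra-tonic excursions accumulate
  desensitization: in vivo, nAChR antagonists raise dopamine during
  purely tonic activity, so tonic firing must leave nAChRs effective.
- **Suppression**
  `S(t) = clamp(D_max·β + D_max·[(max(Δu,0)·a + min(Δu,0)) ∗ ŵ](t)·dt, 0, D_max)`,
  with `ŵ` the unit-area depression kernel, `D_max = D(0)` and `β ∈ [0,1]`
  the tonic background as a fraction of the regional maximum (the 0 / 50 /
  100 % levels of the scenario grid). Availability gates only
  depression-*adding* contributions — desensitized receptors cannot
  transduce new acetylcholine — while relief by pauses is ungated, because
  already-installed depression decays regardless of receptor state.
- **Output** `[DA]_o(t) = [(da(t)·(1 − S(t))/r_DA) ∗ K](t)·dt`, with
  `r_DA` the tonic dopamine-neuron rate when rate normalization is
  requested (scenario runs normalize each population to its own tonic
  frequency; the normalization is a scalar and does not affect any
  ordering or ratio).

With tonic ChI firing the deviation term vanishes and `S ≡ β·D_max`
exactly. The simulator is fully deterministic; randomness exists only in
the synthetic input generators (Gaussian rate jitter, Poisson thinning),
which are seeded.

A consequence of the linear-deviation-then-clamp form worth knowing: a
full pause "banks" negative drive inside the convolution, so a rebound
that follows a pause within one depression-kernel memory adds no *net*
suppression at β = 0 until the pause contribution has left the kernel
window. This is why burst-evoked release is probed with a burst that
extends ~50 ms past rebound onset (below).

### The desensitization gain γ

γ is the one free constant of the model (nothing printed pins the mapping
from supra-tonic rate to desensitization load). It is calibrated against
the multiphasic response itself: the default initial excitation (×3 tonic
for 50 ms) leaves availability at ~0.5 when the rebound begins 200 ms
later (DLS γ ≈ 1.57, NAcc γ ≈ 1.80). This is a deliberately *partial*
version of the observation that nAChRs are hard to re-activate at the
rebound epoch. Full gating (availability → 0) makes the desensitization
component dominant rather than minor: it cancels the rebound's
contribution so completely that adding an initial excitation *raises*
net release in NAcc, inverting the observed deepening of the reduction by
excitation. The half-availability anchor keeps the component real —
ablating it changes outputs only for patterns with supra-tonic
excursions, more in DLS than NAcc — while preserving every qualitative
ordering. The feasible band for the anchor under those joint constraints
is roughly 0.5–0.6 remaining availability; 0.5 is used as the stated
halving.

## Synthetic study conditions

The generators emulate the study conditions rather than replay recorded
spike trains; none of the in vivo patterns are tabulated, so the defaults
are stand-ins chosen once within published constraints and exposed in
`axonbrake.defaults`:

- ChI tonic rate 5 Hz (inside the physiological 3–10 Hz band); dopamine
  tonic rate 4 Hz.
- Multiphasic ChI response: initial excitation ×3 for 50 ms (present in
  roughly half of responses, hence the with/without variants sharing all
  timing outside the excitation window), full pause for 150 ms, rebound
  ×2 for 100 ms starting 200 ms after excitation onset — inside the
  observed ~100–300 ms rebound window.
- Dopamine burst: ×5 tonic for 200 ms, starting 50 ms after excitation
  onset. The burst therefore spans the excitation's suppression window,
  the pause, and the first 50 ms of the rebound, so every phase of the
  multiphasic response acts on some portion of burst-evoked release. The
  placement matters: a burst ending at or before rebound onset makes the
  rebound invisible to the peak measurement, and NAcc's short (68 ms)
  depression window requires overlap with the excitation for the
  excitation to deepen the reduction there.
- Scenario timeline: pattern onset at 600 ms, one full
  desensitization-kernel length (400 ms) of burn-in before any event;
  total duration 1.5 s; peak/AUC measured over the full trace by default
  (an explicit analysis window is configurable).
- Phase envelopes are rectangular by design — output kinetics come from
  the kernels, not the input envelopes.

What the generators do **not** emulate: irregular in vivo spike timing
(rates are piecewise-constant unless jitter or Poisson realization is
requested), correlated ChI/DA fluctuations, spatial heterogeneity of
release sites, and the graded diversity of multiphasic responses. Passing
tests therefore demonstrate the model's response to canonical,
noise-free versions of the study conditions, not robustness across the
biological variability of real recordings.

## Ex vivo validation surface

The paired-pulse pipeline mirrors the slice measurement procedure:
composite transient = conditioning transient + test transient scaled by
`1 − D(isi)` when nAChRs are intact (and by 1 when antagonized — the
model deliberately excludes nAChR-independent short-term depression,
which operates on much longer timescales); the test transient is isolated
by bin-wise subtraction floored at 0; its peak, detected within one
depression-support of the test stimulus (earliest bin on ties), is
normalized to a lone-stimulus reference. This is a consistency surface,
not an independent re-derivation: the kernels were fit from data we
cannot access, so the check demonstrates that the implemented model, run
through the measurement procedure it was built from, returns the curves
it encodes (on/off ratio = `1 − clamp(D(isi))` to 1e-9 across 7–400 ms).

## Model exclusions

Deliberately not modeled: ChI-driven instantaneous dopamine release
(synchronized ChI activation can trigger release directly, but the
suppression threshold sits below the release threshold, making
suppression the dominant in vivo outcome); nAChR-independent short-term
depression (persists over seconds, roughly constant on the ~100 ms
timescales of multiphasic activity); Michaelis–Menten uptake, diffusion
and sensor kinetics; D2/mAChR/GABA signaling (pharmacologically excluded
in the source experiments); spatial microdomain heterogeneity.

## Numerical choices

- `dt` defaults to 1 ms; all convolutions are exact discrete causal
  convolutions (`numpy.convolve`, truncated to the input length, scaled
  by `dt`).
- Area normalization of internal kernels uses the sampled sum (`Σ·dt`),
  so tonic steady states are exact at any `dt`.
- Peak detection everywhere takes the earliest bin on ties.
- Degenerate inputs: a lag exactly at the depression root evaluates to 0;
  zero-peak traces raise rather than return NaN ratios; empty kernel
  tables, negative rates, mismatched grids and out-of-range ISIs raise
  `ValueError` with the offending quantity named.
- Determinism: identical configs and seeds produce byte-identical output
  tables.

## Known limitations

- The rate-to-suppression mapping (deviation from tonic rate, weighted by
  the area-normalized depression kernel, added to the β background and
  clamped) is one consistent realization of the published description;
  the authors' exact state-update rule is in their released MATLAB code,
  which is not consulted here.
- The 1e-5 reading of the depression quadratic exponents is a
  typographical repair; it is strongly supported by the resulting
  support lengths but cannot be confirmed from the text alone.
- The regional DLS-greater-than-NAcc asymmetry of the multiphasic
  reduction holds for patterns containing the initial excitation; for
  pause+rebound-only patterns the long DLS kernel memory lets the pause
  cancel more of the rebound, and the NAcc reduction can be larger.
- Relief and added suppression interact only additively inside the
  clamp; saturation effects at β near 0 or 1 are therefore sharp rather
  than smooth.
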