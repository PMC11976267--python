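"""Inspect the regional brake kernels: depression strength and desensitization.

Builds the default DLS and NAcc parameter sets and prints the quantities
that define the cholinergic brake in each region: the maximal depression of
dopamine release immediately after nAChR activation, how long the
suppression window lasts (the kernel's compact support), and when apparent
nAChR desensitization peaks.
"""

import numpy as np

import axonbrake as ab

for region in ("DLS", "NAcc"):
    params = ab.build_region_params(region)
    lags = np.arange(25.0, 400.0, 0.25)
    raw_level = ab.eval_desensitization_level(params, lags, clamp=False)
    interior = np.where((raw_level[1:-1] > raw_level[:-2]) & (raw_level[1:-1] >= raw_level[2:]))[0]
    print(f"{region}:")
    print(f"  maximal depression D(0)        = {params.depression_max:.3f}")
    print(f"  suppression window (support)   = {params.depression_support:.1f} ms")
    print(f"  depression at 25 ms            = {ab.eval_depression_strength(params, 25.0):.4f}")
    print(f"  desensitization peak lag       = {lags[interior[0] + 1]:.1f} ms")
    print(f"  activatable fraction at 0 ms   = {ab.eval_activatable_fraction(params, 0.0):.2f}")

print(
    "\nA D(0) near 0.87 means a dopamine-axon stimulus arriving immediately"
    "\nafter ChI/nAChR activation releases only ~13% of its unconditioned"
    "\ndopamine in DLS; the brake is weaker (~39% remaining) and roughly"
    "\nthree times shorter-lived in NAcc."
)
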