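"""Config-file driven run: sweep stage, outputs and reproducibility manifest.

Writes a small YAML run configuration, executes it through the same code
path as the ``axonbrake run`` command, and shows the artifacts and the
manifest fields that make the run reproducible.
"""

import json
import tempfile
from pathlib import Path

import yaml

import axonbrake as ab

config = {
    "stage": "sweep",
    "name": "demo-sweep",
    "regions": ["DLS", "NAcc"],
    "betas": [0.0, 0.5, 1.0],
    "chi_patterns": ["multiphasic_with_excitation", "multiphasic_no_excitation"],
    "da_pattern": "burst",
    "duration": 1500.0,
    "seed": 0,
}

with tempfile.TemporaryDirectory() as tmp:
    cfg_path = Path(tmp) / "run.yaml"
    cfg_path.write_text(yaml.safe_dump(config))
    manifest = ab.run_from_config(cfg_path, Path(tmp) / "out")

    print("outputs:", manifest["outputs"])
    print("package_version:", manifest["package_version"])
    print("seed:", manifest["seed"])
    summary = (Path(tmp) / "out" / "sweep_summary.tsv").read_text().splitlines()
    print(f"sweep_summary.tsv: {len(summary) - 1} records "
          "(3 betas x 2 patterns x 2 regions)")
    print(summary[0])
    print(summary[1])

print(
    "\nRe-running the same config and seed reproduces every table"
    "\nbyte-for-byte; the manifest echoes the config and package version."
)
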