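"""Config-file driven pipeline runs, manifests and parameter serialization.

A run configuration is a small YAML document::

    stage: sweep            # simulate | sweep | paired_pulse | validate | generate
    name: fig-style-sweep
    regions: [DLS, NAcc]
    betas: [0.0, 0.5, 1.0]
    chi_patterns: [multiphasic_with_excitation, multiphasic_no_excitation]
    da_pattern: burst
    dt: 1.0
    duration: 1500.0
    seed: 0
    desensitization_enabled: true

Every run writes its outputs plus a ``manifest.json`` (config echo, package
version, seed) sufficient to reproduce it exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import defaults
from .kernels import PolynomialCurve, Region, RegionParams, build_region_params
from .exvivo import depression_curve
from .simulate import SimConfig, resolve_chi_pattern, resolve_da_pattern, scenario_sweep, simulate_dao
from .synth import make_multiphasic_chi, make_tonic_rate
from .traces import write_trace

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_run_config",
    "run_from_config",
    "region_params_to_dict",
    "region_params_from_dict",
    "save_region_params",
    "load_region_params",
]

_STAGES = ("simulate", "sweep", "paired_pulse", "validate", "generate")


class ConfigError(ValueError):
    """Raised for unparseable or schema-invalid run configurations."""


@dataclass(frozen=True)
class RunConfig:
    stage: str
    name: str = "run"
    regions: tuple = ("DLS",)
    betas: tuple = defaults.BETA_LEVELS
    chi_patterns: tuple = ("multiphasic_with_excitation", "multiphasic_no_excitation")
    da_pattern: str = "burst"
    isis: tuple = defaults.PAIRED_PULSE_ISIS
    dt: float = defaults.DT_MS
    duration: float = defaults.DURATION_MS
    seed: int = 0
    desensitization_enabled: bool = True
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ConfigError(f"unknown stage {self.stage!r}; known stages: {', '.join(_STAGES)}")
        for region in self.regions:
            Region.coerce(region)  # raises with the accepted values listed


_KNOWN_KEYS = {f for f in RunConfig.__dataclass_fields__}
_SEQUENCE_KEYS = {"regions", "betas", "chi_patterns", "isis"}


def load_run_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: YAML parse failure: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}; known keys {sorted(_KNOWN_KEYS)}")
    if "stage" not in raw:
        raise ConfigError(f"{path}: missing required key 'stage'")
    for key in _SEQUENCE_KEYS & set(raw):
        if not isinstance(raw[key], (list, tuple)):
            raise ConfigError(f"{path}: key {key!r} must be a list")
        raw[key] = tuple(raw[key])
    try:
        return RunConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _sim_config(cfg: RunConfig, beta: float) -> SimConfig:
    return SimConfig(
        beta=beta,
        desensitization_enabled=cfg.desensitization_enabled,
        dt=cfg.dt,
        duration=cfg.duration,
        da_tonic_rate=defaults.DA_TONIC_HZ,
        seed=cfg.seed,
    )


def run_from_config(path, output_dir=None) -> dict:
    """Execute the stage requested by a config file; return the manifest.

    Writes traces / summary tables as delimited text plus ``manifest.json``
    into the output directory. Raises :class:`ConfigError` for user errors.
    """
    cfg = load_run_config(path)
    outdir = Path(output_dir if output_dir is not None else cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    if cfg.stage == "sweep":
        scenarios = [
            (cfg.da_pattern, chi, beta) for beta in cfg.betas for chi in cfg.chi_patterns
        ]
        params = [build_region_params(r) for r in cfg.regions]
        table = scenario_sweep(scenarios, params, _sim_config(cfg, beta=0.0))
        table.to_csv(outdir / "sweep_summary.tsv", sep="\t", index=False, float_format="%.10g")
        written.append("sweep_summary.tsv")
    elif cfg.stage == "simulate":
        for region in cfg.regions:
            params = build_region_params(region)
            for beta in cfg.betas:
                sim_cfg = _sim_config(cfg, beta)
                da = resolve_da_pattern(cfg.da_pattern, cfg.duration, cfg.dt)
                chi = resolve_chi_pattern(
                    cfg.chi_patterns[0], cfg.duration, cfg.dt, params.tonic_chi_rate
                )
                result = simulate_dao(da, chi, params, sim_cfg)
                stem = f"simulate_{params.region.value}_beta{beta:g}"
                result.to_frame().to_csv(
                    outdir / f"{stem}.tsv", sep="\t", index=False, float_format="%.10g"
                )
                with open(outdir / f"{stem}_summary.json", "w") as fh:
                    json.dump(result.summary(), fh, indent=2)
                written += [f"{stem}.tsv", f"{stem}_summary.json"]
    elif cfg.stage in ("paired_pulse", "validate"):
        frames = []
        for region in cfg.regions:
            params = build_region_params(region)
            frames.append(depression_curve(params, cfg.isis, dt=cfg.dt))
        table = pd.concat(frames, ignore_index=True)
        table.to_csv(outdir / "paired_pulse.tsv", sep="\t", index=False, float_format="%.10g")
        written.append("paired_pulse.tsv")
    elif cfg.stage == "generate":
        for region in cfg.regions:
            params = build_region_params(region)
            for label in cfg.chi_patterns:
                trace = resolve_chi_pattern(label, cfg.duration, cfg.dt, params.tonic_chi_rate)
                if trace is None:
                    continue
                name = f"chi_{params.region.value}_{label}.tsv"
                write_trace(outdir / name, trace)
                written.append(name)
        da = resolve_da_pattern(cfg.da_pattern, cfg.duration, cfg.dt)
        write_trace(outdir / f"da_{cfg.da_pattern}.tsv", da)
        written.append(f"da_{cfg.da_pattern}.tsv")

    from . import __version__

    manifest = {
        "name": cfg.name,
        "stage": cfg.stage,
        "config": asdict(cfg),
        "defaults": defaults.as_dict(),
        "package_version": __version__,
        "seed": cfg.seed,
        "outputs": written,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# Region-parameter serialization (human-readable, nested key-value)


def region_params_to_dict(params: RegionParams) -> dict:
    """RegionParams as a nested dict; coefficient order and units documented."""
    def curve(c: PolynomialCurve) -> dict:
        d = {
            "coefficients_ascending": list(c.coefficients),
            "x_units": "ms",
            "valid_range_ms": list(c.valid_range),
        }
        if c.r_squared is not None:
            d["r_squared"] = c.r_squared
        return d

    return {
        "region": params.region.value,
        "tonic_chi_rate_hz": params.tonic_chi_rate,
        "depression_curve": curve(params.depression_curve),
        "desensitization_curve": curve(params.desensitization_curve),
        "desensitization_convention": params.desensitization_convention,
    }


def region_params_from_dict(data: dict) -> RegionParams:
    def curve(d: dict) -> PolynomialCurve:
        return PolynomialCurve(
            tuple(d["coefficients_ascending"]),
            valid_range=tuple(d.get("valid_range_ms", (0.0, 400.0))),
            r_squared=d.get("r_squared"),
        )

    return RegionParams(
        region=Region.coerce(data["region"]),
        depression_curve=curve(data["depression_curve"]),
        desensitization_curve=curve(data["desensitization_curve"]),
        desensitization_convention=data["desensitization_convention"],
        tonic_chi_rate=float(data.get("tonic_chi_rate_hz", 5.0)),
    )


def save_region_params(path, params: RegionParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(region_params_to_dict(params), fh, sort_keys=False)


def load_region_params(path) -> RegionParams:
    with open(path) as fh:
        return region_params_from_dict(yaml.safe_load(fh))
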