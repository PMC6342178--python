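"""Run configuration: a single YAML file driving the CLI workflows.

Example::

    seed: 1
    output: runs/demo
    variables:
      BottomToTop: data/bt.tif
      LeftToRight: data/lr.tif
    occurrences: data/occurrences.csv
    fit:
      target: ratio            # or f1
      combiner: product        # or geometric_mean
      aic: paper               # or standard
      grid: {rows: 10, cols: 10, levels: 3, shrink: 1.0}
    monte_carlo:
      iterations: 100
      split: true
      train_fraction: 0.7
      jackknife: false
      noise:
        occurrence_sd: 10.0
        environment:
          BottomToTop: {mean: 0.0, sd: 10.0}   # sd/mean may be raster paths
        curve:
          BottomToTop: {sd_x: 10.0, sd_y: 0.0}

All randomness flows from the single master seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fitting import GridSearchConfig
from .montecarlo import EnvNoise, MCConfig, NoiseSpec
from .raster import read_raster

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration; message lists every problem found."""


@dataclass
class RunConfig:
    seed: int = 0
    output: str = "habsuit-output"
    variables: dict[str, str] = field(default_factory=dict)
    occurrences: str | None = None
    curves: dict[str, str] = field(default_factory=dict)
    target: str = "ratio"
    combiner: str = "product"
    aic_convention: str = "paper"
    grid: GridSearchConfig = field(default_factory=GridSearchConfig)
    mc: MCConfig | None = None
    base_dir: Path = field(default_factory=Path)
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def resolve(self, path: str) -> Path:
        p = Path(path)
        return p if p.is_absolute() else self.base_dir / p

    def load_variables(self):
        return {name: read_raster(self.resolve(p)) for name, p in self.variables.items()}


def _parse_grid(d: dict, errors: list[str]) -> GridSearchConfig:
    try:
        return GridSearchConfig(
            grid_rows=int(d.get("rows", 10)),
            grid_cols=int(d.get("cols", 10)),
            levels=int(d.get("levels", 3)),
            shrink=float(d.get("shrink", 1.0)),
            ridge_tolerance=float(d.get("ridge_tolerance", 10.0)),
        )
    except (TypeError, ValueError) as exc:
        errors.append(f"fit.grid: {exc}")
        return GridSearchConfig()


def _parse_noise(d: dict, cfg: RunConfig, errors: list[str]) -> NoiseSpec:
    env: dict[str, EnvNoise] = {}
    for name, spec in (d.get("environment") or {}).items():
        if name not in cfg.variables:
            errors.append(f"noise.environment: unknown variable {name!r}")
            continue
        mean = spec.get("mean", 0.0)
        sd = spec.get("sd", 0.0)
        try:
            mean = float(mean) if not isinstance(mean, str) else read_raster(cfg.resolve(mean))
            sd = float(sd) if not isinstance(sd, str) else read_raster(cfg.resolve(sd))
        except (IOError, ValueError) as exc:
            errors.append(f"noise.environment.{name}: {exc}")
            continue
        env[name] = EnvNoise(mean=mean, sd=sd)
    curve: dict[str, tuple[float, float]] = {}
    for name, spec in (d.get("curve") or {}).items():
        if name not in cfg.variables:
            errors.append(f"noise.curve: unknown variable {name!r}")
            continue
        curve[name] = (float(spec.get("sd_x", 0.0)), float(spec.get("sd_y", 0.0)))
    try:
        occ_sd = float(d.get("occurrence_sd", 0.0))
    except (TypeError, ValueError):
        errors.append("noise.occurrence_sd must be a number")
        occ_sd = 0.0
    try:
        return NoiseSpec(occurrence_sd=occ_sd, environment=env, curve=curve)
    except ValueError as exc:
        errors.append(str(exc))
        return NoiseSpec()


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a run configuration file.

    All validation errors are collected and raised together (ConfigError)
    before any computation starts.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    errors: list[str] = []
    cfg = RunConfig(base_dir=path.parent, raw=raw)
    cfg.seed = int(raw.get("seed", 0))
    cfg.output = str(raw.get("output", "habsuit-output"))
    cfg.variables = {str(k): str(v) for k, v in (raw.get("variables") or {}).items()}
    if not cfg.variables:
        errors.append("at least one entry under 'variables' is required")
    for name, p in cfg.variables.items():
        if not cfg.resolve(p).exists():
            errors.append(f"variables.{name}: raster not found: {p}")
    occ = raw.get("occurrences")
    cfg.occurrences = str(occ) if occ is not None else None
    if cfg.occurrences is not None and not cfg.resolve(cfg.occurrences).exists():
        errors.append(f"occurrences: file not found: {cfg.occurrences}")
    cfg.curves = {str(k): str(v) for k, v in (raw.get("curves") or {}).items()}
    for name, p in cfg.curves.items():
        if not cfg.resolve(p).exists():
            errors.append(f"curves.{name}: file not found: {p}")
    fit = raw.get("fit") or {}
    cfg.target = str(fit.get("target", "ratio"))
    if cfg.target not in ("ratio", "f1"):
        errors.append("fit.target must be 'ratio' or 'f1'")
    cfg.combiner = str(fit.get("combiner", "product"))
    if cfg.combiner not in ("product", "geometric_mean"):
        errors.append("fit.combiner must be 'product' or 'geometric_mean'")
    cfg.aic_convention = str(fit.get("aic", "paper"))
    if cfg.aic_convention not in ("paper", "standard"):
        errors.append("fit.aic must be 'paper' or 'standard'")
    cfg.grid = _parse_grid(fit.get("grid") or {}, errors)
    mc_raw = raw.get("monte_carlo")
    if mc_raw is not None:
        noise = _parse_noise(mc_raw.get("noise") or {}, cfg, errors)
        try:
            cfg.mc = MCConfig(
                iterations=int(mc_raw.get("iterations", 100)),
                train_fraction=float(mc_raw.get("train_fraction", 0.7)),
                split=bool(mc_raw.get("split", False)),
                seed=cfg.seed,
                noise=noise,
                grid=cfg.grid,
                jackknife=bool(mc_raw.get("jackknife", False)),
                target=cfg.target,
                combiner=cfg.combiner,
                aic_convention=cfg.aic_convention,
            )
        except ValueError as exc:
            errors.append(f"monte_carlo: {exc}")
    if errors:
        raise ConfigError(
            f"{path}: invalid configuration:\n  - " + "\n  - ".join(errors)
        )
    return cfg
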