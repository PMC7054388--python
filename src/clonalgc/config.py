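"""Structured run configuration: YAML/JSON loading, validation, round-trip.

A config file has up to four sections — ``model``, ``seeding``, ``solver``
and ``experiment`` — each optional.  Unspecified fields fall back to the
baseline parameterization (n=8, sigma=1.7e-4 ml/cell/day, sigma_c=0.5*sigma,
50+50 founder B-cells, 5000+5000 available Tfh per ml).  Unknown sections or
keys are rejected with field-level messages rather than silently ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .model import GCParameters, MutationKernel, ParameterError, SeedingConfig
from .simulate import SolverSettings

__all__ = ["ConfigError", "RunConfig", "load_config", "loads_config",
           "save_config", "config_to_dict"]

_MODEL_KEYS = {"n", "n_c", "sigma", "sigma_c", "sigma_ratio", "kappa", "d_B",
               "d_G", "eta", "f", "p", "q", "d", "alpha_base",
               "alpha_schedule"}
_SEEDING_KEYS = {"B1_0", "B2_0", "G1_0", "G2_0"}
_SOLVER_KEYS = {"rel_tol", "abs_tol", "t_max", "termination_floor"}
_EXPERIMENT_TYPES = {"simulate", "sweep-sigma", "sweep-seeding", "sweep-p",
                     "thresholds"}
_SECTIONS = {"model", "seeding", "solver", "experiment"}


class ConfigError(ValueError):
    """Malformed configuration: parse failure, unknown key, or bad value."""


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved run configuration."""

    params: GCParameters = field(default_factory=GCParameters)
    seeding: SeedingConfig = field(default_factory=SeedingConfig)
    solver: SolverSettings = field(default_factory=SolverSettings)
    experiment: Mapping[str, Any] = field(default_factory=lambda: {"type": "simulate"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "experiment", dict(self.experiment))
        etype = self.experiment.get("type", "simulate")
        if etype not in _EXPERIMENT_TYPES:
            raise ConfigError(
                f"experiment.type must be one of {sorted(_EXPERIMENT_TYPES)}, "
                f"got {etype!r}"
            )


def _check_keys(section: str, given: Mapping[str, Any], allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{section}' section: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )


def loads_config(raw: Optional[Mapping[str, Any]]) -> RunConfig:
    """Build a validated :class:`RunConfig` from a parsed mapping."""
    raw = dict(raw or {})
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ConfigError(
            f"unknown top-level section(s): {sorted(unknown)}; "
            f"allowed: {sorted(_SECTIONS)}"
        )
    for name in _SECTIONS & set(raw):
        if raw[name] is not None and not isinstance(raw[name], Mapping):
            raise ConfigError(f"section '{name}' must be a mapping")

    model = dict(raw.get("model") or {})
    _check_keys("model", model, _MODEL_KEYS)
    if "sigma_c" in model and "sigma_ratio" in model:
        raise ConfigError(
            "model section sets both 'sigma_c' and 'sigma_ratio'; use one"
        )
    kernel_kwargs = {}
    for src, dst in (("p", "p"), ("q", "q"), ("d", "d_del")):
        if src in model:
            kernel_kwargs[dst] = model.pop(src)
    sigma = model.get("sigma", 1.7e-4)
    if "sigma_ratio" in model:
        model["sigma_c"] = model.pop("sigma_ratio") * sigma
    if "alpha_schedule" in model and model["alpha_schedule"] is not None:
        model["alpha_schedule"] = tuple(model["alpha_schedule"])
    try:
        kernel = MutationKernel(**kernel_kwargs)
        params = GCParameters(kernel=kernel, **model)
    except ParameterError as exc:
        raise ConfigError(f"invalid model parameter: {exc}") from exc

    seeding_raw = dict(raw.get("seeding") or {})
    _check_keys("seeding", seeding_raw, _SEEDING_KEYS)
    try:
        seeding = SeedingConfig(**seeding_raw)
    except ParameterError as exc:
        raise ConfigError(f"invalid seeding: {exc}") from exc

    solver_raw = dict(raw.get("solver") or {})
    _check_keys("solver", solver_raw, _SOLVER_KEYS)
    try:
        solver = SolverSettings(**solver_raw)
    except ValueError as exc:
        raise ConfigError(f"invalid solver settings: {exc}") from exc

    experiment = dict(raw.get("experiment") or {"type": "simulate"})
    experiment.setdefault("type", "simulate")
    return RunConfig(params=params, seeding=seeding, solver=solver,
                     experiment=experiment)


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON — a YAML subset) config file."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return loads_config(raw)


def config_to_dict(cfg: RunConfig) -> dict:
    """Fully resolved plain-dict form of a config (for sidecars and saving)."""
    p = cfg.params
    return {
        "model": {
            "n": p.n, "n_c": p.n_c, "sigma": p.sigma, "sigma_c": p.sigma_c,
            "kappa": p.kappa, "d_B": p.d_B, "d_G": p.d_G, "eta": p.eta,
            "f": p.f, "p": p.kernel.p, "q": p.kernel.q, "d": p.kernel.d_del,
            "alpha_base": p.alpha_base,
            "alpha_schedule": list(p.alpha_schedule) if p.alpha_schedule else None,
        },
        "seeding": {"B1_0": cfg.seeding.B1_0, "B2_0": cfg.seeding.B2_0,
                    "G1_0": cfg.seeding.G1_0, "G2_0": cfg.seeding.G2_0},
        "solver": {"rel_tol": cfg.solver.rel_tol, "abs_tol": cfg.solver.abs_tol,
                   "t_max": cfg.solver.t_max,
                   "termination_floor": cfg.solver.termination_floor},
        "experiment": dict(cfg.experiment),
    }


def save_config(cfg: RunConfig, path) -> None:
    """Write a config so that ``load_config`` round-trips it losslessly."""
    data = config_to_dict(cfg)
    if data["model"]["alpha_schedule"] is None:
        del data["model"]["alpha_schedule"]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
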