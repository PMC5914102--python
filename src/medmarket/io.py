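"""Run configuration (YAML) and result/log writing.

A run config is a small nested YAML document with sections ``network``,
``params``, ``solver``, ``experiments`` and an optional ``output_dir``.
Unknown keys anywhere are rejected before any computation starts, so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .network import ServiceNetwork, generate_synthetic, load_network
from .params import ModelParams, SolverConfig

__all__ = ["ConfigError", "RunConfig", "load_config", "setup_run_log"]


class ConfigError(ValueError):
    """The run configuration violates the schema."""


_NETWORK_KEYS = {"demand", "service_time", "fee_rate", "fee_matrix", "generate"}
_GENERATE_KEYS = {"zones", "demand_range", "time_range", "seed"}
_EXPERIMENT_KEYS = {"doctor_grid", "omega4_grid", "lambda_grid", "n_doctors", "attractiveness_scale"}
_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParams)}
_SOLVER_KEYS = {f.name for f in dataclasses.fields(SolverConfig)}
_TOP_KEYS = {"network", "params", "solver", "experiments", "output_dir"}


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration."""

    network: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    experiments: dict = field(default_factory=dict)
    output_dir: str | None = None
    base_dir: Path = Path(".")

    def __post_init__(self) -> None:
        _check_keys(self.network, _NETWORK_KEYS, "network")
        _check_keys(self.params, _PARAM_KEYS, "params")
        _check_keys(self.solver, _SOLVER_KEYS, "solver")
        _check_keys(self.experiments, _EXPERIMENT_KEYS, "experiments")
        if "generate" in self.network:
            _check_keys(self.network["generate"] or {}, _GENERATE_KEYS, "network.generate")

    def build_network(self) -> ServiceNetwork:
        sec = self.network
        fee_rate = sec.get("fee_rate", 60.0)
        if "generate" in sec:
            g = sec["generate"] or {}
            return generate_synthetic(
                n_zones=int(g.get("zones", 4)),
                demand_range=tuple(g.get("demand_range", (2, 10))),
                time_range=tuple(g.get("time_range", (0.1, 0.45))),
                fee_rate=float(fee_rate),
                seed=g.get("seed"),
            )
        if "demand" not in sec or "service_time" not in sec:
            raise ConfigError("network needs either 'generate' or 'demand' + 'service_time' paths")
        fee_path = sec.get("fee_matrix")
        return load_network(
            self.base_dir / sec["demand"],
            self.base_dir / sec["service_time"],
            fee_rate=None if fee_path else float(fee_rate),
            fee_path=self.base_dir / fee_path if fee_path else None,
        )

    def build_params(self, **overrides) -> ModelParams:
        merged = {**self.params, **overrides}
        return ModelParams(**merged)

    def build_solver_config(self) -> SolverConfig:
        return SolverConfig(**self.solver)


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config root")
    return RunConfig(
        network=raw.get("network") or {},
        params=raw.get("params") or {},
        solver=raw.get("solver") or {},
        experiments=raw.get("experiments") or {},
        output_dir=raw.get("output_dir"),
        base_dir=path.parent,
    )


def setup_run_log(output_dir: str | Path, name: str = "medmarket") -> logging.Logger:
    """Line-oriented run log with timestamps and levels in ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger(f"{name}.{out}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.propagate = False
    return logger


def log_resolved_parameters(logger: logging.Logger, params: ModelParams, config: SolverConfig) -> None:
    """Record the complete resolved parameter set (auditability)."""
    for f in dataclasses.fields(params):
        logger.info("param %s = %r", f.name, getattr(params, f.name))
    for f in dataclasses.fields(config):
        logger.info("solver %s = %r", f.name, getattr(config, f.name))
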