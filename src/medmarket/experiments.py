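"""Sensitivity sweeps, per-pair reports and information-display scenarios.

Each sweep solves the full equilibrium at every grid value and tabulates
the headline waits and utilizations.  Non-converged grid points are kept
in the table with ``converged = False`` and NaN outcomes -- never
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    ConvergenceError,
    EquilibriumResults,
    InsufficientSupplyError,
    MedicalServiceMarket,
    solve_equilibrium,
)
from .network import ServiceNetwork
from .params import FUTILITY_PROFIT, ModelParams, SolverConfig

__all__ = [
    "SweepResult",
    "ScenarioSpec",
    "sweep_doctor_count",
    "sweep_parameter",
    "per_pair_report",
    "find_crossing",
    "nearest_approach",
    "default_scenarios",
    "run_scenarios",
    "DEFAULT_DOCTOR_GRID",
    "DEFAULT_OMEGA4_GRID",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_DOCTOR_GRID = (20, 50, 80, 100, 150)
DEFAULT_OMEGA4_GRID = (0.5, 1.0, 1.5, 2.0, 2.5)
DEFAULT_LAMBDA_GRID = (0.8, 0.9, 1.0, 1.1, 1.2, 1.3)

_RECORD_COLUMNS = [
    "doctor_wait_mode1",
    "doctor_wait_mode2_mean",
    "doctor_wait_mode2_simple_mean",
    "patient_wait_mode1",
    "patient_wait_mode2",
    "utilization_mode1",
    "utilization_mode2",
    "utilization_avg",
    "mode1_share",
    "iterations",
    "residual",
    "converged",
    "mode1_degenerate",
    "error",
]


@dataclass(frozen=True)
class SweepResult:
    """Grid of equilibria for one swept parameter."""

    parameter: str
    grid: tuple[float, ...]
    records: pd.DataFrame
    solutions: tuple[EquilibriumResults | None, ...] = field(repr=False, default=())

    def series(self, column: str) -> np.ndarray:
        return self.records[column].to_numpy(dtype=float)

    @property
    def all_converged(self) -> bool:
        return bool(self.records["converged"].all())


def _record(value: float, res: EquilibriumResults | None, error: str | None = None) -> dict:
    if res is None:
        rec = {c: np.nan for c in _RECORD_COLUMNS}
        rec.update(converged=False, error=error or "failed", iterations=np.nan)
        return rec
    return {
        "doctor_wait_mode1": res.doctor_wait_mode1,
        "doctor_wait_mode2_mean": res.doctor_wait_mode2_mean,
        "doctor_wait_mode2_simple_mean": res.doctor_wait_mode2_simple_mean,
        "patient_wait_mode1": res.patient_wait_mode1,
        "patient_wait_mode2": res.patient_wait_mode2,
        "utilization_mode1": res.utilization_mode1,
        "utilization_mode2": res.utilization_mode2,
        "utilization_avg": res.utilization_avg,
        "mode1_share": res.mode1_share,
        "iterations": res.iterations,
        "residual": res.residual,
        "converged": res.converged,
        "mode1_degenerate": res.mode1_degenerate,
        "error": "",
    }


def _run_grid(net: ServiceNetwork, param_sets: Sequence[tuple[float, ModelParams]], name: str, config) -> SweepResult:
    rows, sols = [], []
    for value, params in param_sets:
        try:
            res = solve_equilibrium(net, params, config)
            rows.append(_record(value, res))
            sols.append(res)
        except (ConvergenceError, InsufficientSupplyError) as exc:
            rows.append(_record(value, None, error=str(exc)))
            sols.append(None)
    records = pd.DataFrame(rows, index=pd.Index([v for v, _ in param_sets], name=name))
    return SweepResult(parameter=name, grid=tuple(v for v, _ in param_sets), records=records, solutions=tuple(sols))


def sweep_doctor_count(
    net: ServiceNetwork,
    params: ModelParams,
    grid: Iterable[float] = DEFAULT_DOCTOR_GRID,
    config: SolverConfig | None = None,
) -> SweepResult:
    """Equilibrium at each doctor count n (N = n doctor-hours)."""
    sets = [(float(n), params.replace(n_doctors=float(n))) for n in grid]
    return _run_grid(net, sets, "n_doctors", config)


def sweep_parameter(
    net: ServiceNetwork,
    params: ModelParams,
    name: str,
    grid: Iterable[float] | None = None,
    config: SolverConfig | None = None,
) -> SweepResult:
    """Sweep the app-mode dispersion ``omega4`` or the profitability
    index ``lam`` (the latter switches to the profit futility variant)."""
    if name == "omega4":
        grid = DEFAULT_OMEGA4_GRID if grid is None else grid
        sets = [(float(v), params.replace(omega4=float(v))) for v in grid]
    elif name == "lam":
        grid = DEFAULT_LAMBDA_GRID if grid is None else grid
        sets = [(float(v), params.replace(lam=float(v), futility_variant=FUTILITY_PROFIT)) for v in grid]
    else:
        raise ValueError(f"unsupported sweep parameter {name!r} (use 'omega4' or 'lam')")
    return _run_grid(net, sets, name, config)


def per_pair_report(
    net: ServiceNetwork,
    params: ModelParams,
    n_doctors: float = 100.0,
    config: SolverConfig | None = None,
) -> pd.DataFrame:
    """Per-pair app-mode doctor waits plus the pooled 'non-app' wait.

    One row per D-P pair labelled ``"i-j"`` and a final ``"non-app"``
    row carrying the uniform in-hospital doctor wait.
    """
    res = solve_equilibrium(net, params.replace(n_doctors=float(n_doctors)), config)
    rows = pd.DataFrame(
        {
            "group": res.network.pair_labels(),
            "doctor_wait": res.allocation.w_id2,
            "service_time": res.network.service_time,
            "demand": res.network.demand,
        }
    )
    non_app = pd.DataFrame(
        {
            "group": ["non-app"],
            "doctor_wait": [res.doctor_wait_mode1],
            "service_time": [np.nan],
            "demand": [res.split.s1],
        }
    )
    return pd.concat([rows, non_app], ignore_index=True)


def find_crossing(grid: Sequence[float], series_a: Sequence[float], series_b: Sequence[float]) -> float | None:
    """Linear-interpolation estimate of where two series intersect.

    Returns the grid point itself if the series touch there, otherwise
    the interpolated location of the first sign change of ``a - b``;
    ``None`` if the difference never changes sign.
    """
    grid = np.asarray(grid, dtype=float)
    d = np.asarray(series_a, dtype=float) - np.asarray(series_b, dtype=float)
    if grid.shape != d.shape:
        raise ValueError("grid and series must be aligned")
    for k in range(len(grid)):
        if d[k] == 0:
            return float(grid[k])
        if k + 1 < len(grid) and np.isfinite(d[k]) and np.isfinite(d[k + 1]) and d[k] * d[k + 1] < 0:
            return float(grid[k] + (grid[k + 1] - grid[k]) * (-d[k]) / (d[k + 1] - d[k]))
    return None


def nearest_approach(grid: Sequence[float], series_a: Sequence[float], series_b: Sequence[float]) -> float:
    """Grid point minimising |a - b| (over finite entries)."""
    grid = np.asarray(grid, dtype=float)
    d = np.abs(np.asarray(series_a, dtype=float) - np.asarray(series_b, dtype=float))
    if not np.isfinite(d).any():
        raise ValueError("no finite differences on the grid")
    return float(grid[np.nanargmin(d)])


# ---------------------------------------------------------------------------
# information-display scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """A labelled set of parameter overrides applied to a base ModelParams."""

    label: str
    overrides: Mapping[str, object] = field(default_factory=dict)

    def resolve(self, base: ModelParams) -> ModelParams:
        return base.replace(**dict(self.overrides))


def default_scenarios(net: ServiceNetwork, attractiveness_scale: float = 5.0) -> tuple[ScenarioSpec, ...]:
    """The three canonical scenarios.

    * ``traditional``: no app channel at all.
    * ``display_patient``: baseline two-mode market (patient disease
      information visible; ``y_j`` as configured, default 0).
    * ``display_both``: doctor registration information also shown;
      encoded as a demand-proportional raise of the patient-information
      attractiveness ``y_j`` (zones generating more demand are more
      attractive to registered doctors), scaled by
      ``attractiveness_scale`` currency units at the mean.
    """
    d, _, _ = net.to_matrices()
    zone_demand = d.sum(axis=0)
    y = (attractiveness_scale * zone_demand / zone_demand.mean()).to_dict()
    return (
        ScenarioSpec("traditional", {"mode2_enabled": False}),
        ScenarioSpec("display_patient", {}),
        ScenarioSpec("display_both", {"attractiveness": y}),
    )


def run_scenarios(
    net: ServiceNetwork,
    params: ModelParams,
    specs: Sequence[ScenarioSpec] | None = None,
    config: SolverConfig | None = None,
) -> pd.DataFrame:
    """Average doctor and patient waits per scenario.

    ``avg_doctor_wait`` is idle hours per idle doctor; ``avg_patient_wait``
    is demand-weighted; per-group simple means are reported alongside.
    """
    specs = default_scenarios(net) if specs is None else specs
    rows = []
    for spec in specs:
        p = spec.resolve(params)
        try:
            res = solve_equilibrium(net, p, config)
            rows.append(
                {
                    "scenario": spec.label,
                    "avg_doctor_wait": res.average_doctor_wait,
                    "avg_patient_wait": res.average_patient_wait,
                    "doctor_wait_mode1": res.doctor_wait_mode1,
                    "doctor_wait_mode2_mean": res.doctor_wait_mode2_mean,
                    "patient_wait_mode1": res.patient_wait_mode1,
                    "patient_wait_mode2": res.patient_wait_mode2,
                    "mode1_share": res.mode1_share,
                    "converged": res.converged,
                    "error": "",
                }
            )
        except (ConvergenceError, InsufficientSupplyError) as exc:
            rows.append({"scenario": spec.label, "converged": False, "error": str(exc)})
    return pd.DataFrame(rows).set_index("scenario")
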