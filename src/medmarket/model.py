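"""Market model and equilibrium solver.

Given a network and parameters, a stationary equilibrium is a mode
split ``Q`` such that the demand split implied by the waiting times it
induces reproduces ``Q`` itself.  The solver has two layers:

*  :func:`stationary_allocation` recovers, for a *given* split, the
   doctor allocation and the doctor waiting times that rationalise it
   under the nested-logit structure.  Flow conservation pins the idle
   flows (every service completed returns one doctor to the idle pool),
   the within-app-mode logit pins the per-pair futilities up to one
   additive level ``kappa``, the mode-choice logit ties the in-hospital
   futility to ``kappa``, and the doctor time budget
   ``N = occupied + idle waiting-hours`` pins ``kappa`` itself.  The
   budget is affine in ``kappa``, so the calibration is a closed-form
   solve plus a finite active-set loop that floors negative waits.

*  :func:`solve_equilibrium` iterates the fixed-point map
   split -> allocation -> patient waits -> costs -> new split with a
   damped step until the relative split change falls below tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core
from .core import (
    DegenerateSplitError,
    DoctorAllocation,
    ModeSplit,
    PatientWaits,
)
from .network import ServiceNetwork, load_example_network, load_network
from .params import FUTILITY_PROFIT, ModelParams, SolverConfig

__all__ = [
    "InnerMultipliers",
    "InsufficientSupplyError",
    "ConvergenceError",
    "stationary_allocation",
    "fixed_point_map",
    "solve_equilibrium",
    "MedicalServiceMarket",
    "EquilibriumResults",
]

#: mode-1 demand share below which the in-hospital market is reported degenerate
DEGENERATE_SHARE = 1e-9


class InsufficientSupplyError(ValueError):
    """Doctor-hours do not cover the occupied service hours."""


class ConvergenceError(RuntimeError):
    """Fixed-point iteration exhausted ``max_iterations``."""

    def __init__(self, message: str, residuals: list[float]):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class InnerMultipliers:
    """Diagnostic Lagrangian multipliers of the inner entropy program.

    ``kappa`` is the additive level of the app-mode futilities fixed by
    the doctor time budget; ``g = kappa / pi_t`` is the uniform
    waiting-time shift.  ``e`` (per pair) and ``f`` are the waiting-time
    multipliers ``pi_t * W``; ``a``, ``b``, ``c`` are the remaining
    multipliers of the program.  ``reproduction_residual`` is the
    maximum error of the closed-form allocation recovered from the
    multipliers (meaningful when no wait was floored).
    """

    kappa: float
    g: float
    a: float
    b: float
    c: float
    e: np.ndarray
    f: float
    reproduction_residual: float
    floored: tuple[str, ...] = ()


def _wait_free_futilities(split: ModeSplit, net: ServiceNetwork, params: ModelParams):
    """Wait-free parts (B2 scalar for mode 1, B1 per pair for mode 2)."""
    f_bar, t_bar, y_bar = core.mode1_averages(split, net, params)
    y = params.zone_attractiveness(net.zones)[net.patient_zone_index()]
    if params.futility_variant == FUTILITY_PROFIT:
        b2 = params.lam * (-f_bar + params.pi_t * t_bar)
        b1 = params.lam * (-net.fee + params.pi_t * net.service_time)
    else:
        b2 = -f_bar + params.pi_t * t_bar - y_bar
        b1 = -net.fee + params.pi_t * (net.service_time + params.z_bar) - y
    return b1, b2


def stationary_allocation(
    split: ModeSplit,
    net: ServiceNetwork,
    params: ModelParams,
    config: SolverConfig | None = None,
) -> tuple[DoctorAllocation, InnerMultipliers]:
    """Doctor allocation and waits rationalising a given mode split.

    Raises
    ------
    InsufficientSupplyError
        If ``N`` does not exceed the occupied hours ``sum(P*t)``.
    DegenerateSplitError
        If either mode carries no demand (the solver clamps shares so
        this never occurs during iteration).
    """
    config = config or SolverConfig()
    occupied = net.occupied_hours
    n_hours = params.total_hours
    if n_hours <= occupied:
        raise InsufficientSupplyError(
            f"insufficient doctor supply: N = {n_hours:g} doctor-hours <= occupied {occupied:g} h"
        )
    if not params.mode2_enabled:
        s1 = split.s1
        if s1 <= 0:
            raise DegenerateSplitError("no demand in the single enabled mode")
        w1 = (n_hours - occupied) / s1
        alloc = DoctorAllocation(
            t_od=net.demand.copy(),
            t_id1_total=s1,
            t_id2=np.zeros(net.n_pairs),
            w_id1=w1,
            w_id2=np.zeros(net.n_pairs),
            occupied_hours=occupied,
            idle_hours_mode1=w1 * s1,
            idle_hours_mode2=0.0,
        )
        mult = InnerMultipliers(0.0, 0.0, 0.0, 0.0, 0.0, np.zeros(net.n_pairs), params.pi_t * w1, 0.0)
        return alloc, mult

    s1, s2 = split.s1, split.s2
    if s1 <= 0 or s2 <= 0:
        raise DegenerateSplitError("both modes must carry demand to rationalise the allocation")
    if (split.q2 <= 0).any():
        raise DegenerateSplitError("every pair needs positive app-mode demand (clamped shares)")

    m = net.n_pairs
    b1, b2 = _wait_free_futilities(split, net, params)
    # within-mode-2 logit: U2_ij = kappa - (1/omega4) ln Q2_ij
    u2_base = -np.log(split.q2) / params.omega4
    # mode-choice logit ties the pooled mode-1 futility to kappa
    u1_base = (
        np.log(m) / params.omega3
        - np.log(s2) / params.omega4
        - np.log(s1 / s2) / params.omega2
    )
    # waits are affine in kappa: W = base + kappa / pi_t
    base = np.concatenate([[(u1_base - b2) / params.pi_t], (u2_base - b1) / params.pi_t])
    weight = np.concatenate([[s1], split.q2])
    idle_target = n_hours - occupied

    free = np.ones(m + 1, dtype=bool)
    kappa = 0.0
    for _ in range(m + 2):
        kappa = params.pi_t * (idle_target - float(weight[free] @ base[free])) / float(weight[free].sum())
        waits = base + kappa / params.pi_t
        newly_negative = (waits < config.wait_floor) & free
        if not newly_negative.any():
            break
        free &= waits >= config.wait_floor
        if not free.any():  # pragma: no cover - impossible for idle_target > 0
            raise RuntimeError("wait floor active on every component")
    waits = np.where(free, np.maximum(base + kappa / params.pi_t, config.wait_floor), config.wait_floor)
    w1 = float(waits[0])
    w2 = waits[1:]
    floored = tuple(
        (["mode1"] if not free[0] else []) + [f"{i}-{j}" for k, (i, j) in enumerate(net.pairs) if not free[k + 1]]
    )

    idle1 = w1 * s1
    idle2 = float(split.q2 @ w2)
    alloc = DoctorAllocation(
        t_od=net.demand.copy(),
        t_id1_total=s1,
        t_id2=split.q2.copy(),
        w_id1=w1,
        w_id2=w2,
        occupied_hours=occupied,
        idle_hours_mode1=idle1,
        idle_hours_mode2=idle2,
    )

    # diagnostics: multipliers in the entropy-program parameterisation
    e = params.pi_t * w2
    f_mult = params.pi_t * w1
    u2 = b1 + e
    u1 = b2 + f_mult
    choice = core.doctor_logsums_and_probs(u1, u2, params, n_pairs=m)
    a_mult = -kappa
    b_mult = -np.log(s1 / m) / params.omega3 - u1
    c_mult = choice.l_id2 - np.log(s2) / params.omega2
    t2_check = np.exp(-params.omega4 * a_mult) * np.exp(-params.omega4 * u2)
    repro = float(np.max(np.abs(t2_check - split.q2))) if not floored else float("nan")
    mult = InnerMultipliers(
        kappa=kappa,
        g=kappa / params.pi_t,
        a=a_mult,
        b=float(b_mult),
        c=float(c_mult),
        e=e,
        f=f_mult,
        reproduction_residual=repro,
        floored=floored,
    )
    return alloc, mult


def _patient_waits(split: ModeSplit, alloc: DoctorAllocation, net: ServiceNetwork, params: ModelParams) -> PatientWaits:
    eff = params.zone_efficiency(net.zones)
    if not params.mode2_enabled:
        w1 = core.patient_wait_mode1(split.s1, alloc.idle_hours_mode1, params, efficiency=eff)
        return PatientWaits(w_p1_zone=np.asarray(w1, dtype=float), w_p2=np.zeros(net.n_pairs))
    w1 = core.patient_wait_mode1(split.s1, alloc.idle_hours_mode1, params, efficiency=eff)
    w2 = core.patient_wait_mode2(split.s2, alloc.idle_hours_mode2, params)
    return PatientWaits(
        w_p1_zone=np.asarray(w1, dtype=float),
        w_p2=np.full(net.n_pairs, w2),
    )


def _apply_map(split: ModeSplit, net: ServiceNetwork, params: ModelParams, config: SolverConfig):
    """One application of the fixed-point map, returning the full state."""
    if not params.mode2_enabled:
        new = ModeSplit(q1=net.demand.copy(), q2=np.zeros(net.n_pairs))
        alloc, mult = stationary_allocation(new, net, params, config)
        waits = _patient_waits(new, alloc, net, params)
        zone_ix = net.patient_zone_index()
        c1, c2 = core.patient_costs(net.fee, net.service_time, waits.w_p1_zone[zone_ix], waits.w_p2, params)
        return new, alloc, mult, waits, c1, c2
    alloc, mult = stationary_allocation(split, net, params, config)
    waits = _patient_waits(split, alloc, net, params)
    zone_ix = net.patient_zone_index()
    w_p1_pair = waits.w_p1_zone[zone_ix]
    c1, c2 = core.patient_costs(net.fee, net.service_time, w_p1_pair, waits.w_p2, params)
    new = core.patient_mode_split(c1, c2, net.demand, params.omega1)
    return new, alloc, mult, waits, c1, c2


def fixed_point_map(
    split: ModeSplit,
    net: ServiceNetwork,
    params: ModelParams,
    config: SolverConfig | None = None,
) -> ModeSplit:
    """The self-map on the split simplex whose fixed points are equilibria."""
    config = config or SolverConfig()
    new, *_ = _apply_map(split, net, params, config)
    return new


def _clamp(split: ModeSplit, net: ServiceNetwork, eps: float) -> ModeSplit:
    q1 = np.clip(split.q1, eps * net.demand, (1.0 - eps) * net.demand)
    return ModeSplit(q1=q1, q2=net.demand - q1)


def solve_equilibrium(
    net: ServiceNetwork,
    params: ModelParams,
    config: SolverConfig | None = None,
    start: ModeSplit | None = None,
) -> "EquilibriumResults":
    """Damped fixed-point iteration to the stationary equilibrium.

    The residual is the maximum per-pair relative split change
    ``max_ij |psi(Q)_ij - Q_ij| / P_ij``.

    Raises :class:`ConvergenceError` (carrying the residual trajectory)
    if ``max_iterations`` is exhausted.
    """
    config = config or SolverConfig()
    eps = config.share_clip
    if start is None:
        frac = config.initial_split_fraction
        split = ModeSplit(q1=frac * net.demand, q2=(1.0 - frac) * net.demand)
    else:
        split = start
    if params.mode2_enabled:
        split = _clamp(split, net, eps)

    theta = config.theta
    prev_res = np.inf
    residuals: list[float] = []
    state = None
    for k in range(config.max_iterations):
        state = _apply_map(split, net, params, config)
        new = state[0]
        res = float(np.max(np.abs(new.q1 - split.q1) / net.demand))
        residuals.append(res)
        if res <= config.tolerance:
            break
        if config.step_rule == "msa":
            step = 1.0 / (k + 1.0)
        elif config.step_rule == "fixed":
            step = config.theta
        else:  # adaptive: halve damping whenever the residual rises
            if res > prev_res:
                theta = max(theta / 2.0, 1e-6)
            step = theta
        prev_res = res
        q1 = split.q1 + step * (new.q1 - split.q1)
        split = ModeSplit(q1=q1, q2=net.demand - q1)
        if params.mode2_enabled:
            split = _clamp(split, net, eps)
    else:
        raise ConvergenceError(
            f"no convergence after {config.max_iterations} iterations (residual {residuals[-1]:.3e})",
            residuals,
        )

    _, alloc, mult, waits, c1, c2 = state
    return EquilibriumResults._build(
        net, params, config, split, alloc, mult, waits, c1, c2,
        iterations=len(residuals), residual=residuals[-1], residual_trajectory=residuals,
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class MedicalServiceMarket:
    """Two-mode doctor-patient service-market model.

    Parameters
    ----------
    network
        The service network (zones, demand, service times, fees).
    params
        Behavioural/market parameters; defaults reproduce the baseline
        four-zone example conditions.

    Examples
    --------
    >>> model = MedicalServiceMarket.example()
    >>> res = model.fit()
    >>> round(res.utilization_avg, 4)
    0.1855
    """

    def __init__(self, network: ServiceNetwork, params: ModelParams | None = None):
        self.network = network
        self.params = params or ModelParams()

    @classmethod
    def from_files(
        cls,
        demand_path,
        time_path,
        fee_rate: float | None = 60.0,
        fee_path=None,
        params: ModelParams | None = None,
    ) -> "MedicalServiceMarket":
        return cls(load_network(demand_path, time_path, fee_rate=fee_rate, fee_path=fee_path), params)

    @classmethod
    def from_matrices(cls, demand, service_time, fee_rate=60.0, fee=None, params=None) -> "MedicalServiceMarket":
        return cls(ServiceNetwork.from_matrices(demand, service_time, fee_rate=fee_rate, fee=fee), params)

    @classmethod
    def example(cls, **param_overrides) -> "MedicalServiceMarket":
        """Model on the bundled four-zone network with baseline parameters."""
        return cls(load_example_network(), ModelParams().replace(**param_overrides))

    def with_params(self, **overrides) -> "MedicalServiceMarket":
        return MedicalServiceMarket(self.network, self.params.replace(**overrides))

    def fit(self, config: SolverConfig | None = None, start: ModeSplit | None = None) -> "EquilibriumResults":
        """Solve for the stationary equilibrium."""
        return solve_equilibrium(self.network, self.params, config, start)

    # sweep/scenario conveniences live in medmarket.experiments
    def sweep_doctor_count(self, grid=(20, 50, 80, 100, 150), config=None):
        from .experiments import sweep_doctor_count

        return sweep_doctor_count(self.network, self.params, grid=grid, config=config)

    def sweep_parameter(self, name: str, grid, config=None):
        from .experiments import sweep_parameter

        return sweep_parameter(self.network, self.params, name, grid, config=config)


@dataclass(frozen=True)
class EquilibriumResults:
    """Converged equilibrium: split, allocation, waits, costs, diagnostics.

    A *degenerate* mode is one whose demand share collapsed to the
    clamping floor; its waits and utilization are reported as NaN
    because no market exists there.
    """

    network: ServiceNetwork
    params: ModelParams
    config: SolverConfig
    split: ModeSplit
    allocation: DoctorAllocation
    multipliers: InnerMultipliers
    waits: PatientWaits
    cost_mode1: np.ndarray
    cost_mode2: np.ndarray
    utilization_mode1: float
    utilization_mode2: float
    utilization_avg: float
    iterations: int
    residual: float
    residual_trajectory: list[float] = field(repr=False)
    mode1_degenerate: bool = False
    mode2_degenerate: bool = False

    converged: bool = True

    @classmethod
    def _build(cls, net, params, config, split, alloc, mult, waits, c1, c2, *, iterations, residual, residual_trajectory):
        total = net.total_demand
        deg1 = split.s1 / total < DEGENERATE_SHARE
        deg2 = params.mode2_enabled and split.s2 / total < DEGENERATE_SHARE
        o1 = float(split.q1 @ net.service_time)
        o2 = float(split.q2 @ net.service_time)
        util1 = np.nan if deg1 else o1 / (o1 + alloc.idle_hours_mode1)
        if not params.mode2_enabled or deg2:
            util2 = np.nan
        else:
            util2 = o2 / (o2 + alloc.idle_hours_mode2)
        util_avg = alloc.occupied_hours / params.total_hours
        return cls(
            network=net, params=params, config=config, split=split, allocation=alloc,
            multipliers=mult, waits=waits, cost_mode1=np.asarray(c1), cost_mode2=np.asarray(c2),
            utilization_mode1=float(util1), utilization_mode2=float(util2),
            utilization_avg=float(util_avg), iterations=iterations, residual=float(residual),
            residual_trajectory=residual_trajectory, mode1_degenerate=bool(deg1),
            mode2_degenerate=bool(deg2),
        )

    # -- headline scalars ---------------------------------------------------

    @property
    def doctor_wait_mode1(self) -> float:
        """Pooled in-hospital idle-doctor wait (h); NaN if the mode collapsed."""
        return np.nan if self.mode1_degenerate else self.allocation.w_id1

    @property
    def doctor_wait_mode2_mean(self) -> float:
        """Demand-weighted mean app-mode doctor wait, idle2 hours / S2 (h)."""
        if not self.params.mode2_enabled or self.mode2_degenerate:
            return np.nan
        return self.allocation.idle_hours_mode2 / self.split.s2

    @property
    def doctor_wait_mode2_simple_mean(self) -> float:
        if not self.params.mode2_enabled or self.mode2_degenerate:
            return np.nan
        return float(np.mean(self.allocation.w_id2))

    @property
    def patient_wait_mode1(self) -> float:
        """Mode-1 patient wait averaged over patient zones, weighted by mode-1 demand (h)."""
        if self.mode1_degenerate:
            return np.nan
        zone_ix = self.network.patient_zone_index()
        w = self.waits.w_p1_zone[zone_ix]
        return float((w * self.split.q1).sum() / self.split.s1)

    @property
    def patient_wait_mode2(self) -> float:
        if not self.params.mode2_enabled or self.mode2_degenerate:
            return np.nan
        return float((self.waits.w_p2 * self.split.q2).sum() / self.split.s2)

    @property
    def average_doctor_wait(self) -> float:
        """Idle hours per idle doctor across both modes (h)."""
        return self.allocation.idle_hours / self.network.total_demand

    @property
    def average_patient_wait(self) -> float:
        """Demand-weighted patient wait across both modes (h)."""
        zone_ix = self.network.patient_zone_index()
        w1 = self.waits.w_p1_zone[zone_ix]
        total = float((w1 * self.split.q1).sum() + (self.waits.w_p2 * self.split.q2).sum())
        return total / self.network.total_demand

    @property
    def mode1_share(self) -> float:
        return self.split.s1 / self.network.total_demand

    # -- tables -------------------------------------------------------------

    def per_pair_table(self) -> pd.DataFrame:
        """One row per D-P pair with split, costs and app-mode doctor wait."""
        zone_ix = self.network.patient_zone_index()
        return pd.DataFrame(
            {
                "pair": self.network.pair_labels(),
                "demand": self.network.demand,
                "service_time": self.network.service_time,
                "fee": self.network.fee,
                "q1": self.split.q1,
                "q2": self.split.q2,
                "share_mode1": self.split.q1 / self.network.demand,
                "cost_mode1": self.cost_mode1,
                "cost_mode2": self.cost_mode2,
                "doctor_wait_mode2": self.allocation.w_id2,
                "patient_wait_mode1": self.waits.w_p1_zone[zone_ix],
                "patient_wait_mode2": self.waits.w_p2,
            }
        )

    def summary(self) -> str:
        """Human-readable solution summary."""
        p = self.params
        lines = [
            "Medical service market equilibrium",
            "==================================",
            f"zones: {len(self.network.zones)}   pairs: {self.network.n_pairs}   "
            f"demand: {self.network.total_demand:g} services/h",
            f"doctor-hours N: {p.total_hours:g}   occupied: {self.allocation.occupied_hours:g} h   "
            f"idle: {self.allocation.idle_hours:.4f} h",
            f"futility variant: {p.futility_variant}   app mode enabled: {p.mode2_enabled}",
            "",
            f"converged in {self.iterations} iterations, residual {self.residual:.2e}",
            "",
            f"{'quantity':38s}{'mode 1':>12s}{'mode 2':>12s}",
            f"{'demand share':38s}{self.mode1_share:12.4f}{1 - self.mode1_share:12.4f}",
            f"{'doctor wait (h)':38s}{self.doctor_wait_mode1:12.4f}{self.doctor_wait_mode2_mean:12.4f}",
            f"{'patient wait (h)':38s}{self.patient_wait_mode1:12.4f}{self.patient_wait_mode2:12.6f}",
            f"{'utilization':38s}{self.utilization_mode1:12.4f}{self.utilization_mode2:12.4f}",
            "",
            f"average utilization: {self.utilization_avg:.4f}",
            f"average doctor wait: {self.average_doctor_wait:.4f} h   "
            f"average patient wait: {self.average_patient_wait:.6f} h",
        ]
        if self.mode1_degenerate or self.mode2_degenerate:
            which = "mode 1" if self.mode1_degenerate else "mode 2"
            lines.append(f"warning: {which} collapsed to the clamping floor (no market)")
        if self.multipliers.floored:
            lines.append(f"warning: waits floored at 0 for: {', '.join(self.multipliers.floored)}")
        return "\n".join(lines)
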