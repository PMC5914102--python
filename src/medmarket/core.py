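"""Elementary model equations.

Patients pay a *full cost* per consultation: the fee plus monetised
waiting and service time.  A multinomial logit over the two modes splits
each pair's demand.  Idle doctors carry a *futility* (monetised
disutility of accepting the next patient); nested logits with logsum
composite values describe which mode and which patient an idle doctor
takes.  Cobb-Douglas meeting functions map unserved demand and idle
doctor waiting-hours to patient waiting times.

Everything here is a pure function of its inputs; market clearing lives
in :mod:`medmarket.model`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import logsumexp

from .network import ServiceNetwork
from .params import FUTILITY_BASE, FUTILITY_PROFIT, ModelParams

__all__ = [
    "ModeSplit",
    "DoctorAllocation",
    "PatientWaits",
    "DoctorChoice",
    "InvalidInputError",
    "DegenerateSplitError",
    "patient_costs",
    "patient_mode_split",
    "mode1_averages",
    "doctor_futility",
    "doctor_logsums_and_probs",
    "patient_wait_mode1",
    "patient_wait_mode2",
]


class InvalidInputError(ValueError):
    """An operation received a physically impossible input."""


class DegenerateSplitError(ValueError):
    """A mode carries (numerically) zero demand; its averages are undefined."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModeSplit:
    """Per-pair demand split between the in-hospital mode (1) and the app mode (2)."""

    q1: np.ndarray
    q2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "q1", np.asarray(self.q1, dtype=float))
        object.__setattr__(self, "q2", np.asarray(self.q2, dtype=float))
        if self.q1.shape != self.q2.shape:
            raise InvalidInputError("q1 and q2 must be aligned")
        if (self.q1 < 0).any() or (self.q2 < 0).any():
            raise InvalidInputError("mode demands must be nonnegative")

    @property
    def total(self) -> np.ndarray:
        return self.q1 + self.q2

    @property
    def s1(self) -> float:
        return float(self.q1.sum())

    @property
    def s2(self) -> float:
        return float(self.q2.sum())


@dataclass(frozen=True)
class DoctorAllocation:
    """Occupied/idle doctor flows and waiting times consistent with a split.

    ``t_od`` are occupied-doctor flows per pair (services completed per
    hour), ``t_id1_total`` the idle flow choosing the in-hospital mode,
    ``t_id2`` the per-pair idle flows on the app mode.  Waits are hours;
    ``w_id1`` is the single pooled in-hospital doctor wait.
    """

    t_od: np.ndarray
    t_id1_total: float
    t_id2: np.ndarray
    w_id1: float
    w_id2: np.ndarray
    occupied_hours: float
    idle_hours_mode1: float
    idle_hours_mode2: float

    def __post_init__(self) -> None:
        if self.w_id1 < 0 or (np.asarray(self.w_id2) < 0).any():
            raise InvalidInputError("doctor waits must be nonnegative")
        if (np.asarray(self.t_od) < 0).any() or self.t_id1_total < 0 or (np.asarray(self.t_id2) < 0).any():
            raise InvalidInputError("doctor flows must be nonnegative")
        flow_gap = abs(float(np.sum(self.t_od)) - (self.t_id1_total + float(np.sum(self.t_id2))))
        if flow_gap > 1e-9 * max(1.0, float(np.sum(self.t_od))):
            raise InvalidInputError(f"occupied/idle flow conservation violated by {flow_gap:g}")

    @property
    def t_id2_total(self) -> float:
        return float(np.sum(self.t_id2))

    @property
    def idle_hours(self) -> float:
        return self.idle_hours_mode1 + self.idle_hours_mode2


@dataclass(frozen=True)
class PatientWaits:
    """Patient waiting times: per patient zone for mode 1, per pair for mode 2."""

    w_p1_zone: np.ndarray
    w_p2: np.ndarray

    def __post_init__(self) -> None:
        if (np.asarray(self.w_p1_zone) < 0).any() or (np.asarray(self.w_p2) < 0).any():
            raise InvalidInputError("patient waits must be nonnegative")


class DoctorChoice(NamedTuple):
    """Doctor-side logsums and choice probabilities."""

    l_id1: float
    l_id2: float
    p3: float          # idle doctor chooses in-hospital mode
    p4: float          # idle doctor chooses app mode
    p5: np.ndarray     # pair choice within mode 1 (sums to 1)
    p6: np.ndarray     # pair choice within mode 2 (sums to 1)


# ---------------------------------------------------------------------------
# patient side
# ---------------------------------------------------------------------------


def patient_costs(
    fee: np.ndarray | float,
    service_time: np.ndarray | float,
    w_p1: np.ndarray | float,
    w_p2: np.ndarray | float,
    params: ModelParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Full healthcare costs of both modes.

    ``C1 = F + mu1*W_p1 + mu2*t`` and
    ``C2 = F + mu1*W_p2 + mu2*t + mu1*Z_bar``.
    """
    fee = np.asarray(fee, dtype=float)
    service_time = np.asarray(service_time, dtype=float)
    w_p1 = np.asarray(w_p1, dtype=float)
    w_p2 = np.asarray(w_p2, dtype=float)
    if (service_time <= 0).any():
        raise InvalidInputError("service times must be positive")
    if (np.minimum(w_p1, w_p2) < 0).any():
        raise InvalidInputError("waiting times must be nonnegative")
    c1 = fee + params.mu1 * w_p1 + params.mu2 * service_time
    c2 = fee + params.mu1 * w_p2 + params.mu2 * service_time + params.mu1 * params.z_bar
    return c1, c2


def patient_mode_split(
    c1: np.ndarray,
    c2: np.ndarray,
    demand: np.ndarray,
    omega1: float,
) -> ModeSplit:
    """Binary logit split of each pair's demand by full cost.

    Infinite cost on one mode sends the whole pair to the other; both
    infinite splits the pair evenly (no information).
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    demand = np.asarray(demand, dtype=float)
    if (demand <= 0).any():
        raise InvalidInputError("pair demand must be positive")
    if omega1 < 0:
        raise InvalidInputError("omega1 must be nonnegative")
    diff = omega1 * (c1 - c2)  # share1 = 1 / (1 + exp(diff))
    both_inf = np.isinf(c1) & np.isinf(c2)
    diff = np.where(both_inf, 0.0, diff)
    diff = np.where(np.isinf(c1) & ~both_inf, np.inf, diff)
    diff = np.where(np.isinf(c2) & ~both_inf, -np.inf, diff)
    with np.errstate(over="ignore"):
        share1 = 1.0 / (1.0 + np.exp(np.clip(diff, -745.0, 745.0)))
    q1 = demand * share1
    return ModeSplit(q1=q1, q2=demand - q1)


# ---------------------------------------------------------------------------
# doctor side
# ---------------------------------------------------------------------------


def mode1_averages(split: ModeSplit, net: ServiceNetwork, params: ModelParams) -> tuple[float, float, float]:
    """Demand-weighted in-hospital averages (F_bar, t_bar, y_bar).

    Idle doctors evaluate the in-hospital mode through its average fee,
    service time and patient-information attractiveness, weighted by
    mode-1 demand.
    """
    s1 = split.s1
    if s1 <= 0:
        raise DegenerateSplitError("mode 1 carries no demand; averages undefined")
    y = params.zone_attractiveness(net.zones)[net.patient_zone_index()]
    f_bar = float((net.fee * split.q1).sum() / s1)
    t_bar = float((net.service_time * split.q1).sum() / s1)
    y_bar = float((y * split.q1).sum() / s1)
    return f_bar, t_bar, y_bar


def doctor_futility(
    fee: np.ndarray | float,
    service_time: np.ndarray | float,
    wait: np.ndarray | float,
    params: ModelParams,
    attractiveness: np.ndarray | float = 0.0,
    include_z_bar: bool = False,
) -> np.ndarray | float:
    """Idle-doctor futility of accepting the next patient.

    Base variant: ``U = -F + pi_t*(W + t [+ Z_bar]) - y`` (the departure
    wait ``Z_bar`` applies on the app mode only).  Profit variant:
    ``U = lam*(-F + pi_t*t) + pi_t*W``.
    """
    fee = np.asarray(fee, dtype=float)
    service_time = np.asarray(service_time, dtype=float)
    wait = np.asarray(wait, dtype=float)
    if params.futility_variant == FUTILITY_PROFIT:
        u = params.lam * (-fee + params.pi_t * service_time) + params.pi_t * wait
    else:
        z = params.z_bar if include_z_bar else 0.0
        u = -fee + params.pi_t * (wait + service_time + z) - np.asarray(attractiveness, dtype=float)
    return u if u.ndim else float(u)


def doctor_logsums_and_probs(
    u_id1: np.ndarray | float,
    u_id2: np.ndarray,
    params: ModelParams,
    n_pairs: int | None = None,
) -> DoctorChoice:
    """Nested-logit structure of idle-doctor choices.

    The logsum of a mode is ``L = -(1/omega) * log sum exp(-omega*U)``
    over its pairs; the upper-level mode choice is a binary logit with
    dispersion ``omega2`` on the two logsums.  A scalar ``u_id1`` means
    the pooled in-hospital futility, identical across ``n_pairs`` pairs.
    """
    u_id2 = np.asarray(u_id2, dtype=float)
    u_id1 = np.asarray(u_id1, dtype=float)
    if u_id1.ndim == 0:
        if n_pairs is None:
            n_pairs = u_id2.size
        u1 = np.full(n_pairs, float(u_id1))
    else:
        u1 = u_id1
    l1 = float(-logsumexp(-params.omega3 * u1) / params.omega3)
    l2 = float(-logsumexp(-params.omega4 * u_id2) / params.omega4)
    d = params.omega2 * (l1 - l2)
    with np.errstate(over="ignore"):
        p3 = float(1.0 / (1.0 + np.exp(np.clip(d, -745.0, 745.0))))
    a5 = -params.omega3 * u1
    p5 = np.exp(a5 - logsumexp(a5))
    a6 = -params.omega4 * u_id2
    p6 = np.exp(a6 - logsumexp(a6))
    return DoctorChoice(l_id1=l1, l_id2=l2, p3=p3, p4=1.0 - p3, p5=p5, p6=p6)


# ---------------------------------------------------------------------------
# meeting functions
# ---------------------------------------------------------------------------


def _cobb_douglas_wait(efficiency: float | np.ndarray, unserved: float, idle_hours: float, params: ModelParams):
    """W = A^(-1/a1) * Q^((1-a1)/a1) * (idle doctor waiting-hours)^(-a2/a1)."""
    a1, a2 = params.alpha1, params.alpha2
    if idle_hours <= 0:
        return np.inf * np.ones_like(np.asarray(efficiency, dtype=float))
    eff = np.asarray(efficiency, dtype=float)
    return eff ** (-1.0 / a1) * unserved ** ((1.0 - a1) / a1) * idle_hours ** (-a2 / a1)


def patient_wait_mode1(
    q1_total: float,
    idle_hours_mode1: float,
    params: ModelParams,
    efficiency: float | np.ndarray = 1.0,
) -> float | np.ndarray:
    """In-hospital patient wait from the Cobb-Douglas meeting function.

    ``idle_hours_mode1`` is the pooled idle doctor waiting-hours
    ``W_id1 * T_id1_total``.  At ``alpha1 = alpha2 = 1`` this reduces to
    ``1 / (A_j * idle_hours_mode1)``.  Zero idle hours signal an
    infinite wait (no doctor ever waits for an in-hospital patient).
    """
    if q1_total < 0 or idle_hours_mode1 < 0:
        raise InvalidInputError("inputs must be nonnegative")
    out = _cobb_douglas_wait(efficiency, q1_total, idle_hours_mode1, params)
    return out if np.ndim(out) else float(out)


def patient_wait_mode2(q2_total: float, idle_hours_mode2: float, params: ModelParams) -> float:
    """App-mode patient wait; same meeting function with the friction
    constant ``a_tilde`` in place of the zone efficiency."""
    if q2_total < 0 or idle_hours_mode2 < 0:
        raise InvalidInputError("inputs must be nonnegative")
    return float(_cobb_douglas_wait(params.a_tilde, q2_total, idle_hours_mode2, params))
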