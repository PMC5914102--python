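"""Behavioural and market parameters, and solver configuration."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["ModelParams", "SolverConfig", "FUTILITY_BASE", "FUTILITY_PROFIT"]

#: futility with fee, activity cost, departure wait and information attractiveness
FUTILITY_BASE = "base"
#: profitability-index variant: U = lam*(-F + pi_t*t) + pi_t*W
FUTILITY_PROFIT = "profit"


@dataclass(frozen=True)
class ModelParams:
    """All behavioural/market parameters of the two-mode service market.

    Monetary values share one currency; times are hours; one unit period
    is one hour, so ``n_doctors`` doctors give ``N = n_doctors`` doctor-hours.

    Attributes
    ----------
    mu1, mu2
        Patient valuation of waiting time and of in-service time (currency/h).
    omega1
        Patient mode-choice logit dispersion.
    omega2, omega3, omega4
        Doctor logit dispersions: mode choice, within in-hospital mode,
        within app mode.  The nesting requires ``omega3 > omega2`` and
        ``omega4 > omega2``.
    alpha1, alpha2
        Meeting-rate elasticities of unserved patients and idle doctors,
        each in (0, 1].
    efficiency
        Zone matching-efficiency ``A_j``: scalar or mapping zone -> value.
    a_tilde
        App-channel friction constant (large = near-frictionless matching).
    pi_t
        Doctor activity (time) cost, currency/h.
    z_bar
        Extra app-mode patient wait caused by doctor departures (h).
    attractiveness
        Patient-information attractiveness ``y_j`` to app-mode doctors
        (currency): scalar or mapping patient zone -> value.
    lam
        Profitability index multiplying doctors' net-income term in the
        profit futility variant.
    n_doctors
        Total doctor activity time N, doctor-hours per unit period.
    futility_variant
        ``"base"`` or ``"profit"`` (profitability-index form).
    mode2_enabled
        False reproduces the traditional, app-free market.
    """

    mu1: float = 20.0
    mu2: float = 10.0
    omega1: float = 0.2
    omega2: float = 0.2
    omega3: float = 0.5
    omega4: float = 0.5
    alpha1: float = 1.0
    alpha2: float = 1.0
    efficiency: float | Mapping[str, float] = 1.0
    a_tilde: float = 1.0e4
    pi_t: float = 10.0
    z_bar: float = 0.0
    attractiveness: float | Mapping[str, float] = 0.0
    lam: float = 1.0
    n_doctors: float = 100.0
    futility_variant: str = FUTILITY_BASE
    mode2_enabled: bool = True

    def __post_init__(self) -> None:
        if min(self.omega1, self.omega2, self.omega3, self.omega4) < 0:
            raise ValueError("dispersion coefficients must be nonnegative")
        if self.mode2_enabled:
            if not (self.omega3 > self.omega2 and self.omega4 > self.omega2):
                raise ValueError("nesting requires omega3 > omega2 and omega4 > omega2")
        for name in ("alpha1", "alpha2"):
            a = getattr(self, name)
            if not 0 < a <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.n_doctors <= 0:
            raise ValueError("n_doctors must be positive")
        if self.a_tilde <= 0:
            raise ValueError("a_tilde must be positive")
        if isinstance(self.efficiency, (int, float)) and self.efficiency <= 0:
            raise ValueError("efficiency must be positive")
        if self.z_bar < 0:
            raise ValueError("z_bar must be nonnegative")
        if self.futility_variant not in (FUTILITY_BASE, FUTILITY_PROFIT):
            raise ValueError(f"unknown futility_variant {self.futility_variant!r}")

    @property
    def total_hours(self) -> float:
        """N: doctor activity hours per unit period (one hour per doctor)."""
        return float(self.n_doctors)

    def replace(self, **overrides) -> "ModelParams":
        names = {f.name for f in dataclasses.fields(self)}
        unknown = set(overrides) - names
        if unknown:
            raise ValueError(f"unknown parameter overrides: {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def _per_zone(self, value: float | Mapping[str, float], zones: tuple[str, ...], name: str) -> np.ndarray:
        if isinstance(value, Mapping):
            missing = set(zones) - set(map(str, value))
            if missing:
                raise ValueError(f"{name} mapping misses zones {sorted(missing)}")
            return np.array([float(value[str(z)]) for z in zones])
        return np.full(len(zones), float(value))

    def zone_efficiency(self, zones: tuple[str, ...]) -> np.ndarray:
        """A_j per zone, in zone order."""
        out = self._per_zone(self.efficiency, zones, "efficiency")
        if (out <= 0).any():
            raise ValueError("efficiency must be positive for every zone")
        return out

    def zone_attractiveness(self, zones: tuple[str, ...]) -> np.ndarray:
        """y_j per patient zone, in zone order."""
        return self._per_zone(self.attractiveness, zones, "attractiveness")


@dataclass(frozen=True)
class SolverConfig:
    """Fixed-point solver settings.

    ``step_rule`` is one of ``"adaptive"`` (damping halves whenever the
    residual rises -- the default), ``"msa"`` (method of successive
    averages, step 1/(k+1)) or ``"fixed"`` (constant ``theta``).
    """

    tolerance: float = 1e-8
    max_iterations: int = 10000
    step_rule: str = "adaptive"
    theta: float = 1.0
    initial_split_fraction: float = 0.7
    root_find_tolerance: float = 1e-10
    wait_floor: float = 0.0
    share_clip: float = 1e-12

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not 0 < self.theta <= 1:
            raise ValueError("theta must lie in (0, 1]")
        if self.step_rule not in ("adaptive", "msa", "fixed"):
            raise ValueError(f"unknown step_rule {self.step_rule!r}")
        if not 0 < self.initial_split_fraction < 1:
            raise ValueError("initial_split_fraction must lie in (0, 1)")
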