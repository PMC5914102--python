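"""Independent entropy-program check of the stationary allocation.

The closed-form allocation of :func:`medmarket.model.stationary_allocation`
is the stationarity point of an entropy-type program over idle-doctor
flows: nested-entropy terms with coefficients ``1/omega2 - 1/omega3``
and ``1/omega2 - 1/omega4`` on the mode totals, ``1/omega3`` and
``1/omega4`` on the per-pair flows, plus the (wait-inclusive) futility
as the linear cost, minimised subject to total idle flow equal to total
demand.  This module re-solves that program with a generic constrained
minimiser and reports the worst disagreement -- a numerical oracle for
tests, never used by the solver itself.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import LinearConstraint, minimize

from .core import ModeSplit
from .model import stationary_allocation, _wait_free_futilities
from .network import ServiceNetwork
from .params import ModelParams, SolverConfig

__all__ = ["OracleUnavailableError", "kkt_oracle_check"]


class OracleUnavailableError(RuntimeError):
    """The generic optimiser failed to converge; no oracle value available."""


def kkt_oracle_check(
    split: ModeSplit,
    net: ServiceNetwork,
    params: ModelParams,
    config: SolverConfig | None = None,
) -> float:
    """Max |entropy-program allocation - closed-form allocation|.

    Intended for small instances (a handful of pairs); the optimisation
    has ``2 * n_pairs`` variables.
    """
    alloc, _ = stationary_allocation(split, net, params, config)
    if alloc.w_id1 == 0 or (alloc.w_id2 == 0).any():
        raise OracleUnavailableError("floored waits break the smooth KKT structure")
    m = net.n_pairs
    b1, b2 = _wait_free_futilities(split, net, params)
    u1 = b2 + params.pi_t * alloc.w_id1          # pooled, identical across pairs
    u2 = b1 + params.pi_t * alloc.w_id2
    a1 = 1.0 / params.omega2 - 1.0 / params.omega4
    a2 = 1.0 / params.omega2 - 1.0 / params.omega3

    def objective(x: np.ndarray) -> float:
        t1, t2 = x[:m], x[m:]
        s1t, s2t = t1.sum(), t2.sum()
        return (
            a2 * s1t * (np.log(s1t) - 1.0)
            + a1 * s2t * (np.log(s2t) - 1.0)
            + (t1 * (np.log(t1) - 1.0)).sum() / params.omega3
            + (t2 * (np.log(t2) - 1.0)).sum() / params.omega4
            + float(t1 @ np.full(m, u1))
            + float(t2 @ u2)
        )

    x0 = np.concatenate([np.full(m, split.s1 / m), np.maximum(split.q2, 1e-6)])
    total = net.total_demand
    res = minimize(
        objective,
        x0,
        method="SLSQP",
        bounds=[(1e-10, None)] * (2 * m),
        constraints=[LinearConstraint(np.ones(2 * m), total, total)],
        options={"maxiter": 3000, "ftol": 1e-14},
    )
    if not res.success:
        raise OracleUnavailableError(f"optimizer failed: {res.message}")
    t1o, t2o = res.x[:m], res.x[m:]
    expected_t1 = np.full(m, split.s1 / m)       # uniform: pooled mode-1 futility
    return float(max(np.abs(t1o - expected_t1).max(), np.abs(t2o - split.q2).max()))
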