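"""Service-network container and constructors.

A network is a set of zones and the ordered doctor-patient (D-P) pairs
``(i, j)`` connecting them.  Each pair carries three fixed, exogenous
quantities: the patient demand rate ``P_ij`` (services/h), the mean
consultation time ``t_ij`` (h) and the consultation fee ``F_ij``
(currency).  Pairs with zero demand are dropped at construction time;
they contribute nothing to any equilibrium quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ServiceNetwork",
    "NetworkLoadError",
    "load_network",
    "load_example_network",
    "generate_synthetic",
]


class NetworkLoadError(ValueError):
    """A matrix file could not be turned into a valid network."""


@dataclass(frozen=True)
class ServiceNetwork:
    """Zones plus per-pair demand, service time and fee.

    Parameters
    ----------
    zones
        Ordered zone labels.
    pairs
        Ordered ``(doctor_zone, patient_zone)`` tuples with positive demand.
    demand, service_time, fee
        Per-pair vectors aligned with ``pairs``.
    """

    zones: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]
    demand: np.ndarray
    service_time: np.ndarray
    fee: np.ndarray

    def __post_init__(self) -> None:
        for name in ("demand", "service_time", "fee"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not self.pairs:
            raise NetworkLoadError("network has no pairs with positive demand")
        if len(set(self.pairs)) != len(self.pairs):
            raise NetworkLoadError("duplicate D-P pair keys")
        n = len(self.pairs)
        for name in ("demand", "service_time", "fee"):
            if getattr(self, name).shape != (n,):
                raise NetworkLoadError(f"{name} must have one entry per pair")
        if not (self.demand > 0).all():
            raise NetworkLoadError("every retained pair must have positive demand")
        if not (self.service_time > 0).all():
            raise NetworkLoadError("service times must be positive")
        if not (self.fee >= 0).all():
            raise NetworkLoadError("fees must be nonnegative")
        unknown = {z for ij in self.pairs for z in ij} - set(self.zones)
        if unknown:
            raise NetworkLoadError(f"pairs reference unknown zones: {sorted(unknown)}")

    # -- derived quantities -------------------------------------------------

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def total_demand(self) -> float:
        """Total patient demand rate (services/h)."""
        return float(self.demand.sum())

    @property
    def occupied_hours(self) -> float:
        """Stationary occupied doctor-hours per unit period, sum of P_ij * t_ij."""
        return float((self.demand * self.service_time).sum())

    def patient_zone_index(self) -> np.ndarray:
        """Index into ``zones`` of the patient zone of each pair."""
        pos = {z: k for k, z in enumerate(self.zones)}
        return np.array([pos[j] for _, j in self.pairs], dtype=int)

    def pair_labels(self) -> list[str]:
        return [f"{i}-{j}" for i, j in self.pairs]

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_matrices(
        cls,
        demand: pd.DataFrame,
        service_time: pd.DataFrame,
        fee_rate: float | None = 60.0,
        fee: pd.DataFrame | None = None,
    ) -> "ServiceNetwork":
        """Build a network from square, zone-labelled matrices.

        Rows are doctor zones, columns patient zones.  Unless an explicit
        ``fee`` matrix is given, ``F_ij = fee_rate * t_ij``.
        """
        d = _check_matrix(demand, "demand")
        t = _check_matrix(service_time, "service_time")
        if list(d.index) != list(t.index) or list(d.columns) != list(t.columns):
            raise NetworkLoadError("demand and service-time matrices must share zone labels and order")
        if fee is not None:
            f = _check_matrix(fee, "fee")
            if list(f.index) != list(d.index):
                raise NetworkLoadError("fee matrix zone labels differ from demand's")
        elif fee_rate is None:
            raise NetworkLoadError("either a fee matrix or a fee_rate is required")
        else:
            f = t * float(fee_rate)
        zones = tuple(str(z) for z in d.index)
        pairs, dv, tv, fv = [], [], [], []
        for i in zones:
            for j in zones:
                p = float(d.loc[i, j])
                if p > 0:
                    pairs.append((i, j))
                    dv.append(p)
                    tv.append(float(t.loc[i, j]))
                    fv.append(float(f.loc[i, j]))
        if not pairs:
            raise NetworkLoadError("all-zero demand matrix: empty network")
        return cls(zones, tuple(pairs), np.array(dv), np.array(tv), np.array(fv))

    def to_matrices(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        """Demand, service-time and fee matrices (zeros on absent pairs)."""
        idx = pd.Index(self.zones, name="zone")
        mats = [pd.DataFrame(0.0, index=idx, columns=list(self.zones)) for _ in range(3)]
        for k, (i, j) in enumerate(self.pairs):
            mats[0].loc[i, j] = self.demand[k]
            mats[1].loc[i, j] = self.service_time[k]
            mats[2].loc[i, j] = self.fee[k]
        return tuple(mats)  # type: ignore[return-value]

    def to_files(self, demand_path: str | Path, time_path: str | Path) -> None:
        d, t, _ = self.to_matrices()
        d.to_csv(demand_path)
        t.to_csv(time_path)


def _check_matrix(df: pd.DataFrame, name: str) -> pd.DataFrame:
    if df.shape[0] != df.shape[1]:
        raise NetworkLoadError(f"{name} matrix is not square: shape {df.shape}")
    df = df.copy()
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if list(df.index) != list(df.columns):
        raise NetworkLoadError(f"{name} matrix row and column labels differ")
    arr = df.to_numpy()
    try:
        arr = arr.astype(float)
    except (TypeError, ValueError) as exc:
        bad = _first_bad_cell(df)
        raise NetworkLoadError(f"{name} matrix has an unparseable cell at {bad}") from exc
    if np.isnan(arr).any():
        raise NetworkLoadError(f"{name} matrix has a missing cell at {_first_bad_cell(df)}")
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise NetworkLoadError(f"{name} matrix has a negative entry at row {df.index[i]}, column {df.columns[j]}")
    return df.astype(float)


def _first_bad_cell(df: pd.DataFrame) -> str:
    for i in df.index:
        for j in df.columns:
            try:
                v = float(df.loc[i, j])
            except (TypeError, ValueError):
                return f"row {i}, column {j}"
            if np.isnan(v):
                return f"row {i}, column {j}"
    return "unknown cell"


def _read_matrix_file(path: str | Path, name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # noqa: BLE001 - surface as a load error
        raise NetworkLoadError(f"cannot read {name} matrix from {path}: {exc}") from exc
    return df


def load_network(
    demand_path: str | Path,
    time_path: str | Path,
    fee_rate: float | None = 60.0,
    fee_path: str | Path | None = None,
) -> ServiceNetwork:
    """Load a network from delimited matrix files (Table 1/Table 2 layout)."""
    demand = _read_matrix_file(demand_path, "demand")
    times = _read_matrix_file(time_path, "service_time")
    fee = _read_matrix_file(fee_path, "fee") if fee_path is not None else None
    return ServiceNetwork.from_matrices(demand, times, fee_rate=fee_rate, fee=fee)


def load_example_network(fee_rate: float = 60.0) -> ServiceNetwork:
    """The bundled four-zone, 12-pair example network."""
    base = resources.files("medmarket") / "data"
    with resources.as_file(base / "demand.csv") as d, resources.as_file(base / "service_time.csv") as t:
        return load_network(d, t, fee_rate=fee_rate)


def generate_synthetic(
    n_zones: int,
    demand_range: tuple[float, float] = (2, 10),
    time_range: tuple[float, float] = (0.1, 0.45),
    fee_rate: float = 60.0,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> ServiceNetwork:
    """Seeded random network with a zero-diagonal integer demand matrix.

    Demand entries are integers drawn uniformly from ``demand_range``,
    service times uniform in ``time_range`` and fees ``fee_rate * t``.
    Identical seeds produce byte-identical matrix files.
    """
    if n_zones < 2:
        raise ValueError("need at least 2 zones")
    lo, hi = demand_range
    tlo, thi = time_range
    if lo <= 0 or hi < lo or tlo <= 0 or thi < tlo:
        raise ValueError("demand and time ranges must be positive and ordered")
    rng = np.random.default_rng(seed)
    zones = tuple(str(k + 1) for k in range(n_zones))
    d = rng.integers(int(round(lo)), int(round(hi)) + 1, size=(n_zones, n_zones)).astype(float)
    t = np.round(rng.uniform(tlo, thi, size=(n_zones, n_zones)), 4)
    np.fill_diagonal(d, 0.0)
    dd = pd.DataFrame(d, index=pd.Index(zones, name="zone"), columns=list(zones))
    tt = pd.DataFrame(t, index=pd.Index(zones, name="zone"), columns=list(zones))
    net = ServiceNetwork.from_matrices(dd, tt, fee_rate=fee_rate)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dd.to_csv(out / "demand.csv")
        tt.to_csv(out / "service_time.csv")
    return net
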