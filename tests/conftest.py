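import numpy as np
import pandas as pd
import pytest

from medmarket import (
    ModelParams,
    ModeSplit,
    ServiceNetwork,
    SolverConfig,
    load_example_network,
    sweep_doctor_count,
    sweep_parameter,
)

DOCTOR_GRID = (20, 50, 80, 100, 150)


@pytest.fixture(scope="session")
def example_net() -> ServiceNetwork:
    return load_example_network()


@pytest.fixture(scope="session")
def base_params() -> ModelParams:
    return ModelParams()


@pytest.fixture()
def solver_cfg() -> SolverConfig:
    return SolverConfig()


@pytest.fixture(scope="session")
def initial_split(example_net) -> ModeSplit:
    return ModeSplit(q1=0.7 * example_net.demand, q2=0.3 * example_net.demand)


@pytest.fixture(scope="session")
def doctor_sweep(example_net, base_params):
    """Solved equilibria over the doctor-count grid (shared across tests)."""
    return sweep_doctor_count(example_net, base_params, grid=DOCTOR_GRID)


@pytest.fixture(scope="session")
def lambda_sweep(example_net, base_params):
    return sweep_parameter(example_net, base_params, "lam")


@pytest.fixture(scope="session")
def omega4_sweep(example_net, base_params):
    return sweep_parameter(example_net, base_params, "omega4")


def make_network(demand: np.ndarray, times: np.ndarray, fee_rate: float = 60.0) -> ServiceNetwork:
    zones = [str(k + 1) for k in range(demand.shape[0])]
    idx = pd.Index(zones, name="zone")
    return ServiceNetwork.from_matrices(
        pd.DataFrame(demand, index=idx, columns=zones),
        pd.DataFrame(times, index=idx, columns=zones),
        fee_rate=fee_rate,
    )


@pytest.fixture(scope="session")
def symmetric_two_pair_net() -> ServiceNetwork:
    """Two zones, two fully symmetric pairs."""
    return make_network(np.array([[0.0, 5.0], [5.0, 0.0]]), np.array([[0.1, 0.2], [0.2, 0.1]]))


@pytest.fixture(scope="session")
def asymmetric_two_pair_net() -> ServiceNetwork:
    return make_network(np.array([[0.0, 5.0], [8.0, 0.0]]), np.array([[0.1, 0.3], [0.2, 0.1]]))
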