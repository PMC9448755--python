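import numpy as np
import pytest
from scipy.optimize import linprog

from paleopop.ethnography import filter_foragers
from paleopop.hindcast import derive_predictor_cube
from paleopop.synth import (SyntheticWorldConfig, default_responses,
                            generate_ethnographic_table,
                            generate_paleoclimate_cube)


def lp_linear_quantile(x, y, tau):
    """Linear τ-quantile regression by linear programming (oracle).

    min Σ τ u⁺ + (1−τ) u⁻ s.t. y = a + b x + u⁺ − u⁻, u± ≥ 0.
    Returns (a, b).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    A = np.column_stack([np.ones(n), x])
    # variables: a+, b+, a-, b-, u+, u-
    c = np.concatenate([np.zeros(4), tau * np.ones(n), (1 - tau) * np.ones(n)])
    A_eq = np.hstack([A, -A, np.eye(n), -np.eye(n)])
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=[(0, None)] * (4 + 2 * n),
                  method="highs")
    assert res.success
    beta = res.x[:2] - res.x[2:4]
    return float(beta[0]), float(beta[1])


@pytest.fixture(scope="session")
def world_config():
    return SyntheticWorldConfig(seed=1)


@pytest.fixture(scope="session")
def responses():
    return default_responses()


@pytest.fixture(scope="session")
def forager_records(world_config, responses):
    records = generate_ethnographic_table(world_config, responses)
    kept, _ = filter_foragers(records)
    return kept


@pytest.fixture(scope="session")
def paleo_world(world_config):
    cube, ice = generate_paleoclimate_cube(world_config)
    return cube, ice


@pytest.fixture(scope="session")
def predictor_cube(paleo_world):
    cube, _ = paleo_world
    return derive_predictor_cube(cube)
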