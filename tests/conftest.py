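import numpy as np
import pytest

from isolim.foodweb import (Compartment, FoodWebModel, LIMProblem,
                            build_pelagic_foodweb)
from isolim.scenarios import build_problem, get_scenario


@pytest.fixture(scope="session")
def model():
    return build_pelagic_foodweb()


@pytest.fixture(scope="session")
def mesohaline():
    return get_scenario("diazo_mesohaline")


@pytest.fixture(scope="session")
def mesohaline_problem(mesohaline):
    problem, _ = build_problem(mesohaline)
    return problem


@pytest.fixture(scope="session")
def random_balanced_flows(model):
    """A strictly positive, exactly mass-balanced flow vector (not required
    to satisfy the physiological priors)."""
    rng = np.random.default_rng(42)
    E, _, _ = model.mass_balance()
    from scipy.linalg import null_space
    Z = null_space(E)
    base = Z @ (Z.T @ np.ones(model.n_flows))  # balanced projection of 1s
    for _ in range(1000):
        x = base + 0.2 * (Z @ rng.standard_normal(Z.shape[1]))
        if np.all(x > 0.05):
            assert np.abs(E @ x).max() < 1e-10
            return x
    raise RuntimeError("could not draw a positive balanced vector")


def simplex_problem(n: int = 3) -> LIMProblem:
    """Uniform-measure test polytope {sum x = 1, x >= 0} wrapped as a LIM."""
    comps = [Compartment(f"C{i}") for i in range(n)] + [
        Compartment("SRC", external=True)]
    flows = [("SRC", f"C{i}") for i in range(n)]
    m = FoodWebModel(comps, flows)
    return LIMProblem(
        model=m, E=np.ones((1, n)), f=np.array([1.0]),
        A=np.zeros((0, n)), b=np.zeros(0), sigma=np.zeros(0),
        G=np.eye(n), h=np.zeros(n),
        inequality_names=[f"nonneg_{i}" for i in range(n)],
    )
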