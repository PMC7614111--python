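import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def gaussian_toy3():
    """3 locations at distances 0, 1, 2 from loc0; known means, sd 1."""
    from bgwr.simulate import simulate_gaussian_toy

    return simulate_gaussian_toy(3, [1.0, 2.0, 3.0], 1.0, 20, seed=11)


@pytest.fixture(scope="session")
def nb_small_lattice():
    """5x5 negative binomial lattice, m=20 — small but structured."""
    from bgwr.simulate import SimulationSpec, simulate_lattice

    ds, truth = simulate_lattice(SimulationSpec(grid_u=5, grid_v=5, m=20, seed=3))
    return ds, truth


def pooled_mcse(x: np.ndarray) -> float:
    """Monte-Carlo standard error of a posterior mean via arviz ESS."""
    import arviz as az

    ess = float(az.ess(np.atleast_2d(x)))
    return float(np.std(x) / np.sqrt(max(ess, 1.0)))
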