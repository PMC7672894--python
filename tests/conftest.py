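import numpy as np
import pytest

from vafmix import (
    BetaComponent,
    BetaParetoMixture,
    ParetoComponent,
    SimulationConfig,
    simulate_tumour,
)


def make_model(betas, weights, tail=None):
    """Construct a parameterised (unfitted) mixture for oracle tests.

    betas: list of (a, b); tail: (scale, shape) or None; weights in
    canonical order (tail first when present, Betas by decreasing mean).
    """
    m = BetaParetoMixture(n_beta=len(betas), tail=tail is not None)
    m.betas_ = [BetaComponent(a=a, b=b) for a, b in betas]
    m.tail_ = None if tail is None else ParetoComponent(scale=tail[0], shape=tail[1])
    m.weights_ = np.asarray(weights, dtype=float)
    m.nll_ = np.nan
    m.lambda_ = m._lambda()
    m.n_ = 0
    m.converged_ = True
    m.n_iter_ = 0
    m.fit_trace_ = np.asarray([])
    m.responsibilities_ = None
    m.scores_ = None
    return m


def beta_ab(mean, var):
    c = mean * (1 - mean) / var - 1.0
    return mean * c, (1 - mean) * c


@pytest.fixture(scope="session")
def recovery_model():
    """The well-separated generative model used in recovery studies:
    Pareto(shape 1.5, scale 0.05) tail + Beta peaks at 0.5 and 0.25
    (variance 0.002), mixing proportions (0.3, 0.4, 0.3)."""
    return make_model(
        betas=[beta_ab(0.5, 0.002), beta_ab(0.25, 0.002)],
        weights=[0.3, 0.4, 0.3],
        tail=(0.05, 1.5),
    )


@pytest.fixture(scope="session")
def driver_tumour():
    """One default driver simulation shared across tests."""
    return simulate_tumour(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def neutral_tumour():
    """One default no-driver simulation shared across tests."""
    return simulate_tumour(SimulationConfig(seed=43, driver_time=None))
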