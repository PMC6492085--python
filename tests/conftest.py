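import numpy as np
import pytest

from jointmeta.simulate import SimulationScenario, simulate_dataset


@pytest.fixture(scope="session")
def toy_scenario():
    """Two small studies with moderate association (fast to fit)."""
    return SimulationScenario(K=2, n_per_study=60, name="toy")


@pytest.fixture(scope="session")
def toy_dataset(toy_scenario):
    return simulate_dataset(toy_scenario, seed=202)


@pytest.fixture(scope="session")
def null_scenario():
    """No association, no between-study heterogeneity."""
    return SimulationScenario(
        K=2,
        n_per_study=80,
        alpha2=0.0,
        alpha3=0.0,
        A=((0.0, 0.0), (0.0, 0.0)),
        name="null",
    )


@pytest.fixture(scope="session")
def null_dataset(null_scenario):
    return simulate_dataset(null_scenario, seed=77)
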