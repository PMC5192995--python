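import numpy as np
import pytest

from vesselnorm import (
    ModelSpec,
    SaemSettings,
    default_design,
    kpl4_population,
    population_fit,
    saem_fit,
    simulate_trial,
)
from vesselnorm.trial import PopulationModel, TrialDesign


@pytest.fixture(scope="session")
def pop():
    return kpl4_population()


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def trial(pop, design):
    """One default synthetic trial (dataset, truth table), fixed seed."""
    return simulate_trial(pop, design, rng_seed=42)


@pytest.fixture(scope="session")
def literature_init(pop):
    init = dict(pop.theta)
    init["T0"] = 70.0
    return init


@pytest.fixture(scope="session")
def quick_settings(literature_init):
    """Shortened SAEM schedule for fits shared across tests."""
    return SaemSettings(seed=3, n_burnin=200, n_smooth=150, n_chains=1,
                        init_theta=literature_init, init_b=0.2)


@pytest.fixture(scope="session")
def transient_fit(trial, quick_settings):
    data, _ = trial
    return saem_fit(data, ModelSpec(structural="transient"), quick_settings)


@pytest.fixture(scope="session")
def truth_fit(trial, pop):
    """FitResult pinned at the generating population (no estimation)."""
    data, _ = trial
    theta = dict(pop.theta)
    theta["T0"] = 70.0 * np.exp(-0.5 * np.log1p(0.3**2))  # log-normal median
    omega = dict(pop.omega)
    omega["T0"] = float(np.sqrt(np.log1p(0.3**2)))
    return population_fit(data, ModelSpec(), theta, omega, pop.b)


@pytest.fixture(scope="session")
def control_pop():
    """Control-arm-only population (no treatment parameters)."""
    return PopulationModel(
        theta={"alpha_T": 0.109, "alpha_V": 0.119, "K": 1.14},
        omega={"alpha_T": 0.422, "alpha_V": 0.177, "K": 0.711},
        b=0.185,
        group_map={"control": {}},
    )


@pytest.fixture(scope="session")
def control_design():
    return TrialDesign(arms=(("control", 20),))
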