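import numpy as np
import pandas as pd
import pytest

from eggsig import rejection, synthdata
from eggsig.pattern import DistanceStandardization


@pytest.fixture(scope="session")
def population():
    """Default synthetic two-species population (seeded)."""
    return synthdata.generate_population(synthdata.PopulationConfig(seed=1))


@pytest.fixture(scope="session")
def hosts(population):
    return population[population["species"] == "host"]


@pytest.fixture(scope="session")
def parasites(population):
    return population[population["species"] == "parasite"]


@pytest.fixture(scope="session")
def experiments(population):
    return synthdata.generate_experiments(population, seed=2)


@pytest.fixture(scope="session")
def pooled_std(population):
    return DistanceStandardization.fit(population)


@pytest.fixture(scope="session")
def distance_fit(experiments, population, pooled_std):
    X, y = rejection.build_design(experiments, population, model="distance", std=pooled_std)
    return rejection.fit_rejection_glm(X, y)


def make_fit(intercept: float, slope: float) -> rejection.RejectionModelFit:
    """Hand-built single-predictor logistic fit for simulation tests."""
    params = pd.Series({"const": intercept, "pattern_distance": slope})
    return rejection.RejectionModelFit(
        predictor_names=["pattern_distance"],
        params=params,
        bse=params * 0.0,
        llf=0.0,
        aic=0.0,
        adjusted_r2=0.0,
        mcfadden_r2=0.0,
        vifs=None,
        n=0,
        null_deviance=0.0,
        deviance=0.0,
    )
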