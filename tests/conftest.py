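import numpy as np
import pandas as pd
import pytest

from subhealth import (
    build_model,
    default_population,
    sample_cohort,
    subhealth_model,
)
from subhealth.simulate import PopulationModel


@pytest.fixture(scope="session")
def spec():
    return subhealth_model()


@pytest.fixture(scope="session")
def population():
    return default_population()


@pytest.fixture(scope="session")
def cohort(population):
    """Mid-sized synthetic cohort shared across tests."""
    return sample_cohort(population, n=1500, seed=20230822)


@pytest.fixture(scope="session")
def small_population():
    """A three-construct chain with a formative middle block, for oracle checks."""
    spec = build_model(
        [
            ("A", "reflective", ["a1", "a2", "a3"]),
            ("B", "formative", ["b1", "b2"]),
            ("C", "reflective", ["c1", "c2"]),
        ],
        [("A", "B"), ("B", "C")],
    )
    return PopulationModel(
        spec=spec,
        loadings={"a1": 0.8, "a2": 0.7, "a3": 0.6, "c1": 0.85, "c2": 0.75},
        formative_weights={"b1": 0.6, "b2": 0.5},
        formative_indicator_correlation=0.4,
        path_coefficients={("A", "B"): 0.45, ("B", "C"): 0.35},
    )


def exact_correlation_data(R, n, seed=0):
    """n samples whose *sample* correlation matrix equals R exactly."""
    rng = np.random.default_rng(seed)
    p = R.shape[0]
    Z = rng.standard_normal((n, p))
    Z = Z - Z.mean(axis=0)
    # whiten empirically, then impose R
    S = (Z.T @ Z) / (n - 1)
    W = np.linalg.cholesky(np.linalg.inv(S))
    X = (Z @ W) @ np.linalg.cholesky(R).T
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
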