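import numpy as np
import pytest

from radbio import (
    CohortSpec,
    DoseVolumeHistogram,
    FractionationScheme,
    load_registry,
)


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def scheme():
    """Study fractionation: 60 Gy in 5 fractions of 12 Gy."""
    return FractionationScheme(60.0, 5)


@pytest.fixture
def step_cumulative():
    """Cumulative DVH with points (0,1), (60,0.5), (70,0)."""
    return DoseVolumeHistogram(
        "x", np.array([0.0, 60.0, 70.0]), np.array([1.0, 0.5, 0.0]), "cumulative"
    )


def random_differential_dvh(rng: np.random.Generator, n_bins: int = 40) -> DoseVolumeHistogram:
    """Random normalised differential DVH on a random increasing grid."""
    edges = np.concatenate([[0.0], np.sort(rng.uniform(0.5, 80.0, n_bins))])
    vols = rng.dirichlet(np.ones(n_bins) * 0.5)
    return DoseVolumeHistogram("rand", edges, vols, "differential")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort_spec():
    return CohortSpec(n_patients=6, seed=7)
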