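import numpy as np
import pytest

from glvnet import CommunityModel, growth_rates_for_equilibrium


@pytest.fixture
def two_taxon_model() -> CommunityModel:
    """Hand-checkable 2-taxon community."""
    return CommunityModel(
        taxa=["taxon_a", "taxon_b"],
        r=[1.0, -1.0],
        A=[[-1.0, 0.0], [0.5, -0.5]],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_stable_community(
    rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random (A, y_bar) with a stable interior equilibrium.

    Diagonally dominant rows with negative diagonal guarantee that
    diag(y_bar) A is Hurwitz (Gershgorin).
    """
    A = rng.uniform(-0.3, 0.3, size=(n, n))
    np.fill_diagonal(A, 0.0)
    row = np.abs(A).sum(axis=1)
    np.fill_diagonal(A, -(row + rng.uniform(0.5, 1.0, size=n)))
    y_bar = rng.uniform(0.05, 1.0, size=n)
    return A, y_bar


def stable_model(rng: np.random.Generator, n: int):
    A, y_bar = random_stable_community(rng, n)
    r = growth_rates_for_equilibrium(A, y_bar)
    taxa = [f"t{i}" for i in range(n)]
    return CommunityModel(taxa, r, A), y_bar
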