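from fractions import Fraction

import numpy as np
import pytest

from gtcentrality import BinaryFeatureMatrix, GeneNetwork, datasets


@pytest.fixture
def example_matrix() -> BinaryFeatureMatrix:
    """4 genes × 3 samples; supports {g1,g3}, {g1,g3}, {g2,g3,g4}."""
    return datasets.example_matrix()


@pytest.fixture
def example_network() -> GeneNetwork:
    """14 genes, 11 edges, g14 isolated; hub g4 carries leaves g8-g10."""
    return datasets.example_network()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


def random_rational_weights(
    network: GeneNetwork, rng: np.random.Generator
) -> dict[str, Fraction]:
    """Nonnegative random rationals, one per node (exact-arithmetic friendly)."""
    return {
        g: Fraction(int(rng.integers(0, 7)), int(rng.integers(1, 7)))
        for g in network.nodes
    }
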