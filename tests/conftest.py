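import numpy as np
import pytest

from crossld.core import LineHapFreqs


def random_hap_freqs(rng: np.random.Generator) -> LineHapFreqs:
    return LineHapFreqs(*rng.dirichlet(np.ones(4)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220208)


@pytest.fixture
def random_hap_pairs():
    """Factory for lists of random valid (hA, hB) haplotype-frequency pairs."""

    def make(k: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        return [
            (random_hap_freqs(rng), random_hap_freqs(rng))
            for _ in range(k)
        ]

    return make
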