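import numpy as np
import pytest

from fitscape.landscape import table_from_arrays
from fitscape.synthetic import SyntheticLandscapeConfig, generate_landscape


@pytest.fixture(scope="session")
def default_landscape():
    """Full C=3 synthetic landscape with default (epistatic) parameters."""
    return generate_landscape(SyntheticLandscapeConfig(seed=1))


@pytest.fixture(scope="session")
def additive_landscape_with_effects():
    """C=3 landscape without epistasis, plus its generating effect tables."""
    return generate_landscape(
        SyntheticLandscapeConfig(seed=3, sigma_epistasis=0.0), return_effects=True
    )


@pytest.fixture(scope="session")
def small_landscape():
    """C=2 landscape (4096 genotypes) for fast end-to-end runs."""
    return generate_landscape(SyntheticLandscapeConfig(seed=2, codon_count=2))


@pytest.fixture()
def toy_table():
    """Four 9-mers, one inviable."""
    return table_from_arrays(
        ["AAAAAAAAA", "AAAAAAAAC", "AAAAAAAAG", "AAAAAAAAT"],
        [0.1, -0.7, 0.0, 0.3],
    )


def random_sequences(n, length, seed):
    rng = np.random.default_rng(seed)
    return ["".join(rng.choice(list("ACGT"), length)) for _ in range(n)]


@pytest.fixture()
def random_pool():
    """24 distinct random 9-mers with random fitness."""
    rng = np.random.default_rng(42)
    seqs = []
    seen = set()
    while len(seqs) < 24:
        s = "".join(rng.choice(list("ACGT"), 9))
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    return table_from_arrays(seqs, rng.normal(0, 0.3, size=24))
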