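import itertools

import pytest

from spscore import Alignment, GeneratorConfig, generate_alignment, identity_matrix
from spscore.synthetic import STRUCTURES


@pytest.fixture
def worked_3seq() -> Alignment:
    """The hand-checked three-sequence example used throughout the docs."""
    return Alignment(("s1", "s2", "s3"), ("AC-GT", "A--GT", "ACCGT"), alphabet="ACGT")


@pytest.fixture
def identity_1_0():
    return identity_matrix(1, 0)


def build_corpus(n_seeds: int = 250):
    """Seeded random alignments: n in [2,12], L in [1,60], density in [0,0.8],
    all four gap-structure modes."""
    corpus = []
    for seed in range(n_seeds):
        for struct in STRUCTURES:
            cfg = GeneratorConfig(
                n=2 + seed % 11,
                L=1 + (seed * 7) % 60,
                gap_density=(seed % 9) / 10,
                structure=struct,
                seed=seed,
            )
            corpus.append((cfg, generate_alignment(cfg)))
    return corpus


@pytest.fixture(scope="session")
def corpus():
    return build_corpus()


def all_pairs(n: int):
    return itertools.combinations(range(n), 2)
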