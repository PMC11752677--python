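import numpy as np
import pytest

from mitokit import (
    CircularGenome,
    RecombPairSpec,
    SimulationConfig,
    SSRSpec,
    TandemSpec,
    DispersedSpec,
    TransferSpec,
    generate_genome,
)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def three_pair_study():
    """The default recombination study: a 50 kb circle carrying two inverted
    and one direct recombination-active pair (>= 200 bp, 100% identity)."""
    config = SimulationConfig(
        genome_len=50_000,
        seed=7,
        recomb_pairs=[
            RecombPairSpec(400, "inverted"),
            RecombPairSpec(300, "inverted"),
            RecombPairSpec(250, "direct"),
        ],
    )
    return (*generate_genome(config), config)


@pytest.fixture(scope="session")
def planted_feature_study():
    """A 60 kb circle with planted SSRs of all unit sizes, tandem arrays,
    dispersed pairs of all four orientation classes, and plastome transfers."""
    config = SimulationConfig(
        genome_len=60_000,
        seed=42,
        ssrs=[
            SSRSpec("A", 10), SSRSpec("T", 12), SSRSpec("AT", 5), SSRSpec("AG", 7),
            SSRSpec("CTT", 4), SSRSpec("ACG", 5), SSRSpec("ATCG", 3), SSRSpec("AATC", 4),
            SSRSpec("AATGC", 3), SSRSpec("ACGTC", 3), SSRSpec("AATCGG", 3),
            SSRSpec("ACGTAC", 3),
        ],
        tandems=[TandemSpec(27, 2), TandemSpec(9, 3), TandemSpec(12, 4)],
        dispersed=[
            DispersedSpec(40, "forward", 0),
            DispersedSpec(35, "palindromic", 3),
            DispersedSpec(50, "reverse", 1),
            DispersedSpec(45, "complement", 2),
            DispersedSpec(60, "palindromic", 0),
        ],
        recomb_pairs=[RecombPairSpec(300, "inverted"), RecombPairSpec(250, "direct")],
        transfers=[TransferSpec(1000, 1.0), TransferSpec(500, 0.95),
                   TransferSpec(300, 0.90)],
    )
    return (*generate_genome(config), config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_circle(rng):
    """A 1 kb random circle used to build hand-checked recombination cases."""
    return CircularGenome("toy", random_dna(rng, 1000))
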