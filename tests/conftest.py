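import random

import pytest

from partprov import AlignmentParams, Plasmid, PlasmidCorpus


@pytest.fixture
def params():
    return AlignmentParams()


def random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def make_plasmid(pid, sequence, lab="lab0", topology="linear"):
    return Plasmid(id=pid, sequence=sequence, lab=lab, topology=topology)


@pytest.fixture
def seeded_rng():
    return random.Random(12345)


def plant_block(rng, block, flank_lo=80, flank_hi=140):
    """A random sequence containing ``block`` away from the ends."""
    return (
        random_seq(rng, rng.randint(flank_lo, flank_hi))
        + block
        + random_seq(rng, rng.randint(flank_lo, flank_hi))
    )


def mutate(rng, seq, positions):
    out = list(seq)
    for pos in positions:
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


def small_corpus(rng, n=8, length=250, n_labs=3):
    plasmids = [
        Plasmid(
            id=f"p{i}",
            sequence=random_seq(rng, length),
            lab=f"lab{i % n_labs}",
            topology="linear",
        )
        for i in range(n)
    ]
    return PlasmidCorpus(plasmids)
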