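import itertools

import numpy as np
import pytest

from metalsplice.hexamers import HexamerScoreTable, NUCLEOTIDES


def make_constant_table(ese=2.0, ess=1.0, cls="E"):
    """Complete table assigning every hexamer the same scores/class."""
    return HexamerScoreTable(
        {
            "".join(p): (ese, ess, cls)
            for p in itertools.product(NUCLEOTIDES, repeat=6)
        }
    )


def make_random_table(rng, p_neutral=0.3):
    """Complete table with log-normal scores and random E/S/N classes."""
    entries = {}
    for p in itertools.product(NUCLEOTIDES, repeat=6):
        cls = "N" if rng.random() < p_neutral else ("E" if rng.random() < 0.5 else "S")
        entries["".join(p)] = (
            float(np.exp(rng.normal(0, 0.5))),
            float(np.exp(rng.normal(0, 0.5))),
            cls,
        )
    return HexamerScoreTable(entries)


def random_seq(rng, n):
    return "".join(rng.choice(list(NUCLEOTIDES), size=n))


@pytest.fixture
def constant_table():
    return make_constant_table()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
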