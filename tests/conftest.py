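import numpy as np
import pytest

from tdssgrn.simulation import TimeSeriesDataset
from tdssgrn.tdss_core import (
    Chromosome,
    ParamIntervals,
    RGEPGene,
    SymbolAlphabet,
    encode_delay,
    tail_length,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def alphabet():
    """{*2,*3} over x1..x5 plus R."""
    return SymbolAlphabet(arities=(2, 3), n_genes=5)


@pytest.fixture
def intervals():
    return ParamIntervals()


def make_gene(alphabet, head, tail, rate=1.0, kinetic=None, delays=None,
              delay_max=3):
    """Build a gene with explicit symbols and per-position parameters."""
    L = len(head) + len(tail)
    assert len(tail) == tail_length(alphabet.max_arity, len(head))
    kinetic = np.asarray(kinetic if kinetic is not None else np.zeros(L),
                         dtype=float)
    delays = list(delays) if delays is not None else [0] * L
    bits = np.stack([encode_delay(d, delay_max) for d in delays])
    return RGEPGene(alphabet=alphabet, head=tuple(head), tail=tuple(tail),
                    rate_constant=float(rate), kinetic_orders=kinetic,
                    delay_bits=bits, delay_max=delay_max)


@pytest.fixture
def paper_style_chromosome():
    """The worked example: production *3 over (x3, x1, x2), consumption *4
    over (x2, x4, x1, x3); function set {*2..*5}, head length 2."""
    ab = SymbolAlphabet(arities=(2, 3, 4, 5), n_genes=5)
    g1 = make_gene(ab, head=["*3", "x3"], tail=["x1", "x2"] + ["x5"] * 7,
                   rate=1.5, kinetic=np.arange(11) / 10.0,
                   delays=[0, 1, 2, 0] + [0] * 7)
    g2 = make_gene(ab, head=["*4", "x2"], tail=["x4", "x1", "x3"] + ["x5"] * 6,
                   rate=0.5, kinetic=np.arange(11) / 20.0,
                   delays=[0, 0, 1, 3, 2] + [0] * 6)
    return Chromosome(g1, g2)


@pytest.fixture
def toy_dataset():
    """3 genes x 5 time points, dt = 1, strictly positive."""
    times = np.arange(5.0)
    values = np.array([
        [1.0, 2.0, 3.0, 4.0, 5.0],
        [2.0, 1.5, 1.0, 0.8, 0.6],
        [0.5, 1.0, 2.0, 4.0, 8.0],
    ])
    return TimeSeriesDataset(times=times, values=values)
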