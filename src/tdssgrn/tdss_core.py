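"""Time-delayed S-system model and its linear (GEP-style) chromosome encoding.

A target gene's dynamics follow a power-law rate equation

    dX_i/dt = alpha_i * prod_j X_j(t - tau_gij)^g_ij
            - beta_i  * prod_j X_j(t - tau_hij)^h_ij

where each regulator level is read at an integer lag ``tau`` counted in
sampling intervals.  Candidate equations are encoded as chromosomes of two
fixed-length genes (production and consumption term) joined by subtraction.
Each gene has a head (functions or terminals) and a tail (terminals only)
read level-order into an expression tree, plus one kinetic-order slot and
one delay slot per position and a single rate constant.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from typing import Callable, Optional, Tuple

import numpy as np

__all__ = [
    "ConfigurationError",
    "SymbolAlphabet",
    "ParamIntervals",
    "RGEPGene",
    "Chromosome",
    "TDSSTerm",
    "TDSSEquation",
    "tail_length",
    "delay_bit_width",
    "encode_delay",
    "decode_delay_bits",
    "random_gene",
    "random_chromosome",
    "expressed_length",
    "decode_gene",
    "decode_chromosome",
    "evaluate_term",
    "evaluate_derivative",
]

CONSTANT_SYMBOL = "R"


class ConfigurationError(ValueError):
    """Raised for structurally invalid model or run configurations."""


def tail_length(n: int, h: int) -> int:
    """Tail length guaranteeing a complete level-order tree: ``(n-1)*h + 1``.

    Parameters
    ----------
    n : largest function arity in the alphabet (>= 2)
    h : head length (>= 1)
    """
    if h < 1:
        raise ConfigurationError(f"head length must be >= 1, got {h}")
    if n < 2:
        raise ConfigurationError(f"max arity must be >= 2, got {n}")
    return (n - 1) * h + 1


def delay_bit_width(delay_max: int) -> int:
    """Number of bits needed to encode integer lags in ``[0, delay_max]``."""
    if delay_max < 0:
        raise ConfigurationError(f"delay_max must be >= 0, got {delay_max}")
    return max(1, math.ceil(math.log2(delay_max + 1)))


def encode_delay(value: int, delay_max: int) -> np.ndarray:
    """Encode an integer lag as a fixed-width bit vector (MSB first)."""
    if not 0 <= value <= delay_max:
        raise ConfigurationError(f"delay {value} outside [0, {delay_max}]")
    w = delay_bit_width(delay_max)
    return np.array([(value >> (w - 1 - i)) & 1 for i in range(w)], dtype=np.uint8)


def decode_delay_bits(bits: np.ndarray, delay_max: int) -> int:
    """Decode a bit vector to a lag, wrapped into ``[0, delay_max]``.

    Wrapping (modulo ``delay_max + 1``) keeps every bit pattern decodable so
    bit-flip mutation can never produce an out-of-range lag.  For
    ``delay_max = 2**w - 1`` (e.g. the default 3) the map is the identity.
    """
    value = 0
    for b in bits:
        value = (value << 1) | int(b)
    return value % (delay_max + 1)


@dataclass(frozen=True)
class SymbolAlphabet:
    """Function set (multiplication arities) plus terminal set.

    Function symbols are ``"*m"`` — the product of ``m`` operands.  Terminal
    symbols are the gene variables ``x1 .. xN`` (1-based, matching the usual
    notation; internal gene indices are 0-based) and optionally the constant
    terminal ``R``.
    """

    arities: Tuple[int, ...]
    n_genes: int
    include_constant: bool = True

    def __post_init__(self) -> None:
        if not self.arities:
            raise ConfigurationError("function set must not be empty")
        if any(a < 2 for a in self.arities):
            raise ConfigurationError("every function arity must be >= 2")
        if self.n_genes < 1:
            raise ConfigurationError("need at least one gene variable")

    @property
    def max_arity(self) -> int:
        return max(self.arities)

    @property
    def function_symbols(self) -> Tuple[str, ...]:
        return tuple(f"*{a}" for a in self.arities)

    @property
    def terminal_symbols(self) -> Tuple[str, ...]:
        xs = tuple(f"x{j + 1}" for j in range(self.n_genes))
        return xs + (CONSTANT_SYMBOL,) if self.include_constant else xs

    @property
    def all_symbols(self) -> Tuple[str, ...]:
        return self.function_symbols + self.terminal_symbols

    def arity(self, symbol: str) -> int:
        if symbol.startswith("*"):
            return int(symbol[1:])
        return 0

    def is_function(self, symbol: str) -> bool:
        return symbol.startswith("*")

    def is_terminal(self, symbol: str) -> bool:
        return symbol in self.terminal_symbols

    @staticmethod
    def terminal_index(symbol: str) -> Optional[int]:
        """0-based gene index of an ``xj`` terminal; ``None`` for ``R``."""
        if symbol == CONSTANT_SYMBOL:
            return None
        m = re.fullmatch(r"x(\d+)", symbol)
        if m is None:
            raise ValueError(f"not a terminal symbol: {symbol!r}")
        return int(m.group(1)) - 1


@dataclass(frozen=True)
class ParamIntervals:
    """Closed sampling/clipping intervals for the three coding regions."""

    rate: Tuple[float, float] = (0.0, 3.0)
    kinetic: Tuple[float, float] = (0.0, 1.0)
    delay: Tuple[int, int] = (0, 3)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("rate", self.rate), ("kinetic", self.kinetic),
                               ("delay", self.delay)):
            if hi < lo:
                raise ConfigurationError(f"empty {name} interval [{lo}, {hi}]")
        if self.delay[0] != 0:
            raise ConfigurationError("delay interval must start at 0")

    @property
    def delay_max(self) -> int:
        return int(self.delay[1])


@dataclass
class RGEPGene:
    """One fixed-length gene: symbols plus per-position parameter slots.

    ``kinetic_orders`` and ``delay_bits`` carry one slot per position
    (``h + t`` of each); only positions holding an expressed terminal
    contribute to the decoded term.  Delays are stored as fixed-width bit
    rows (MSB first) so binary genetic operators act on raw bits.
    """

    alphabet: SymbolAlphabet
    head: Tuple[str, ...]
    tail: Tuple[str, ...]
    rate_constant: float
    kinetic_orders: np.ndarray
    delay_bits: np.ndarray  # shape (h + t, bit_width), uint8
    delay_max: int = 3

    @property
    def head_length(self) -> int:
        return len(self.head)

    @property
    def symbols(self) -> Tuple[str, ...]:
        return self.head + self.tail

    def __len__(self) -> int:
        return len(self.head) + len(self.tail)

    @property
    def delays(self) -> np.ndarray:
        """Integer lags decoded from the per-position bit rows."""
        return np.array(
            [decode_delay_bits(row, self.delay_max) for row in self.delay_bits],
            dtype=np.int64,
        )

    def copy(self) -> "RGEPGene":
        return replace(
            self,
            kinetic_orders=self.kinetic_orders.copy(),
            delay_bits=self.delay_bits.copy(),
        )

    def validate(self, intervals: Optional[ParamIntervals] = None) -> None:
        """Assert every structural invariant; raises ``ConfigurationError``."""
        ab = self.alphabet
        t_expected = tail_length(ab.max_arity, len(self.head))
        if len(self.tail) != t_expected:
            raise ConfigurationError(
                f"tail length {len(self.tail)} != (n-1)*h+1 = {t_expected}")
        legal_head = set(ab.all_symbols)
        legal_tail = set(ab.terminal_symbols)
        for s in self.head:
            if s not in legal_head:
                raise ConfigurationError(f"illegal head symbol {s!r}")
        for s in self.tail:
            if s not in legal_tail:
                raise ConfigurationError(f"illegal tail symbol {s!r}")
        L = len(self)
        if self.kinetic_orders.shape != (L,):
            raise ConfigurationError("kinetic_orders must have one slot per position")
        w = delay_bit_width(self.delay_max)
        if self.delay_bits.shape != (L, w):
            raise ConfigurationError("delay_bits must be (positions, bit_width)")
        if not np.isin(self.delay_bits, (0, 1)).all():
            raise ConfigurationError("delay_bits must be 0/1")
        if intervals is not None:
            lo, hi = intervals.rate
            if not lo <= self.rate_constant <= hi:
                raise ConfigurationError(
                    f"rate constant {self.rate_constant} outside [{lo}, {hi}]")
            klo, khi = intervals.kinetic
            if (self.kinetic_orders < klo).any() or (self.kinetic_orders > khi).any():
                raise ConfigurationError("kinetic order outside interval")
            if (self.delays > intervals.delay_max).any():
                raise ConfigurationError("delay outside interval")


@dataclass
class Chromosome:
    """Two genes joined by subtraction: production minus consumption."""

    gene1: RGEPGene
    gene2: RGEPGene
    fitness: Optional[float] = None
    partition_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gene1.alphabet != self.gene2.alphabet:
            raise ConfigurationError("genes must share one alphabet")
        if self.gene1.head_length != self.gene2.head_length:
            raise ConfigurationError("genes must share one head length")

    @property
    def genes(self) -> Tuple[RGEPGene, RGEPGene]:
        return (self.gene1, self.gene2)

    def copy(self) -> "Chromosome":
        return Chromosome(self.gene1.copy(), self.gene2.copy(),
                          fitness=self.fitness, partition_id=self.partition_id)

    # -- one-line text form for logs / checkpoints --------------------------
    # grammar:  gene := head|tail ; rate ; k1,k2,... ; bits1,bits2,...
    #           chromosome := gene − gene
    def to_text(self) -> str:
        return f"{_gene_to_text(self.gene1)} - {_gene_to_text(self.gene2)}"

    @classmethod
    def from_text(cls, text: str, alphabet: SymbolAlphabet,
                  delay_max: int = 3) -> "Chromosome":
        left, right = [p.strip() for p in text.split(" - ")]
        return cls(_gene_from_text(left, alphabet, delay_max),
                   _gene_from_text(right, alphabet, delay_max))


def _gene_to_text(g: RGEPGene) -> str:
    head = " ".join(g.head)
    tail = " ".join(g.tail)
    ks = ",".join(repr(float(v)) for v in g.kinetic_orders)
    bits = ",".join("".join(str(int(b)) for b in row) for row in g.delay_bits)
    return f"{head}|{tail} ; {g.rate_constant!r} ; {ks} ; {bits}"


def _gene_from_text(text: str, alphabet: SymbolAlphabet, delay_max: int) -> RGEPGene:
    sym_part, rate_part, k_part, b_part = [p.strip() for p in text.split(" ; ")]
    head_s, tail_s = sym_part.split("|")
    head = tuple(head_s.split())
    tail = tuple(tail_s.split())
    rate = float(rate_part)
    ks = np.array([float(v) for v in k_part.split(",")])
    bits = np.array([[int(c) for c in token] for token in b_part.split(",")],
                    dtype=np.uint8)
    return RGEPGene(alphabet, head, tail, rate, ks, bits, delay_max=delay_max)


# ---------------------------------------------------------------------------
# random construction
# ---------------------------------------------------------------------------

def random_gene(alphabet: SymbolAlphabet, h: int, intervals: ParamIntervals,
                rng: np.random.Generator) -> RGEPGene:
    """Sample a legal gene uniformly: head from F∪T, tail from T, parameters
    uniform within their intervals."""
    if not alphabet.arities or not alphabet.terminal_symbols:
        raise ConfigurationError("alphabet must have functions and terminals")
    t = tail_length(alphabet.max_arity, h)
    all_syms = alphabet.all_symbols
    terms = alphabet.terminal_symbols
    head = tuple(all_syms[i] for i in rng.integers(0, len(all_syms), size=h))
    tail = tuple(terms[i] for i in rng.integers(0, len(terms), size=t))
    L = h + t
    rate = rng.uniform(*intervals.rate)
    ks = rng.uniform(intervals.kinetic[0], intervals.kinetic[1], size=L)
    dmax = intervals.delay_max
    delays = rng.integers(0, dmax + 1, size=L)
    bits = np.stack([encode_delay(int(d), dmax) for d in delays])
    return RGEPGene(alphabet, head, tail, float(rate), ks, bits, delay_max=dmax)


def random_chromosome(alphabet: SymbolAlphabet, h: int, intervals: ParamIntervals,
                      rng: np.random.Generator) -> Chromosome:
    return Chromosome(random_gene(alphabet, h, intervals, rng),
                      random_gene(alphabet, h, intervals, rng))


# ---------------------------------------------------------------------------
# decoding (level-order / Karva reading)
# ---------------------------------------------------------------------------

def expressed_length(gene: RGEPGene) -> int:
    """Length of the expressed prefix under level-order tree filling.

    Position 0 is the root; each function symbol consumes its arity of
    subsequent positions breadth-first.  The tail-of-terminals construction
    guarantees the prefix closes before the gene ends.
    """
    syms = gene.symbols
    needed = 1
    pos = 0
    while pos < needed:
        needed += gene.alphabet.arity(syms[pos])
        pos += 1
    return needed


@dataclass(frozen=True)
class TDSSTerm:
    """One power-law term: ``rate * constant_factor * prod_k X_{j_k}(t-tau_k)^e_k``."""

    rate: float
    factors: Tuple[Tuple[int, float, int], ...]  # (gene index, exponent, lag)
    constant_factor: float = 1.0

    def __post_init__(self) -> None:
        for j, e, tau in self.factors:
            if tau < 0 or tau != int(tau):
                raise ConfigurationError(f"lag must be a nonnegative integer, got {tau}")

    def value(self, lookup: Callable[[int, int], float]) -> float:
        """Evaluate given ``lookup(gene_index, lag) -> level``."""
        out = self.rate * self.constant_factor
        for j, e, tau in self.factors:
            x = lookup(j, tau)
            if x <= 0 and e != int(e):
                raise ValueError(
                    f"nonpositive level {x} for gene {j} with noninteger exponent {e}")
            out *= x ** e
        return out


@dataclass(frozen=True)
class TDSSEquation:
    """Decoded chromosome: ``dX_i/dt = production - consumption``."""

    target_index: int
    production: TDSSTerm
    consumption: TDSSTerm

    @property
    def max_delay(self) -> int:
        lags = [tau for _, _, tau in self.production.factors + self.consumption.factors]
        return max(lags, default=0)

    def regulators(self) -> set:
        return {j for j, _, _ in self.production.factors + self.consumption.factors}


def decode_gene(gene: RGEPGene) -> TDSSTerm:
    """Decode the expressed prefix of a gene into one power-law term.

    Expressed ``xj`` terminals contribute a factor using that position's
    kinetic-order and delay slots, in level-order position order.  Expressed
    ``R`` terminals multiply ``exp(kinetic_order)`` into the constant factor
    (positive by construction) and carry no delay or exponent.
    """
    n_expr = expressed_length(gene)
    syms = gene.symbols
    delays = gene.delays
    factors = []
    constant = 1.0
    for pos in range(n_expr):
        s = syms[pos]
        if gene.alphabet.is_function(s):
            continue
        j = SymbolAlphabet.terminal_index(s)
        if j is None:
            constant *= math.exp(float(gene.kinetic_orders[pos]))
        else:
            factors.append((j, float(gene.kinetic_orders[pos]), int(delays[pos])))
    return TDSSTerm(rate=float(gene.rate_constant), factors=tuple(factors),
                    constant_factor=constant)


def decode_chromosome(chrom: Chromosome, target_index: int = 0) -> TDSSEquation:
    """Production from gene1, consumption from gene2, joined by subtraction."""
    return TDSSEquation(
        target_index=target_index,
        production=decode_gene(chrom.gene1),
        consumption=decode_gene(chrom.gene2),
    )


def evaluate_term(term: TDSSTerm, lookup: Callable[[int, int], float]) -> float:
    return term.value(lookup)


def evaluate_derivative(eq: TDSSEquation,
                        history: Callable[[int, int], float]) -> float:
    """Rate of change of the target gene given a delayed-level lookup.

    ``history(j, tau)`` must resolve every (gene, lag) pair the equation
    references, already bound to the evaluation time by the caller.
    """
    return eq.production.value(history) - eq.consumption.value(history)
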