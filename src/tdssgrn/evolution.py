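"""Fitness evaluation and hybrid GA/GEP variation and selection operators.

A chromosome carries three coding regions and each has its own operators:

* structure (gene symbol strings) — single-point / single-gene /
  all-variables mutation, single-point / single-gene crossover;
* real parameters (rate constants, kinetic orders) — Gaussian per-slot
  mutation ``X' = X + delta`` and the arithmetic crossover
  ``X' = X + gamma (X - Y)``, ``Y' = Y - gamma (X - Y)`` with gamma decaying
  geometrically over iterations;
* binary delay bits — per-bit inversion, single-point and two-point bit
  crossover.

Fitness is ``1 / (1 + SSE)`` where SSE sums squared deviations between the
decoupled simulation of the target gene and its observed trajectory over
all replicates and time points; invalid (divergent) simulations score 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._fastsim import rk4_decoupled_batch
from .simulation import IntegratorConfig, TimeSeriesDataset
from .tdss_core import (
    Chromosome,
    ConfigurationError,
    ParamIntervals,
    RGEPGene,
    SymbolAlphabet,
    TDSSEquation,
    decode_chromosome,
    expressed_length,
    random_gene,
)

__all__ = [
    "IncompatibleParentsError",
    "EvolutionConfig",
    "Population",
    "FitnessEvaluator",
    "fitness",
    "mutate_structure",
    "mutate_real",
    "mutate_binary",
    "mutate_chromosome",
    "crossover_structure",
    "crossover_real",
    "gamma_schedule",
    "crossover_binary",
    "crossover_chromosomes",
    "roulette_select",
]

logger = logging.getLogger(__name__)

STRUCTURE_MUTATIONS = ("single_point", "single_gene", "all_variables")
STRUCTURE_CROSSOVERS = ("single_point", "single_gene")
BINARY_CROSSOVERS = ("single_point", "two_point")


class IncompatibleParentsError(ValueError):
    """Parents with mismatched alphabets, head lengths or region sizes."""


@dataclass
class EvolutionConfig:
    """Run parameters; defaults follow the benchmark configuration."""

    population_size: int = 2000
    max_iterations: int = 200
    p_c: float = 0.7
    p_m: float = 0.3
    rate_interval: Tuple[float, float] = (0.0, 3.0)
    kinetic_interval: Tuple[float, float] = (0.0, 1.0)
    delay_interval: Tuple[int, int] = (0, 3)
    partitions: int = 200
    head_length: int = 2
    function_set: Tuple[int, ...] = (2, 3, 4, 5)
    include_constant: bool = True
    seed: int = 0
    sigma_fraction: float = 0.1  # Gaussian mutation scale as fraction of interval
    sigma_decay: float = 1.0  # per-iteration geometric decay of that scale
    gamma0: float = 1.0
    elitism: bool = True
    target_fitness: float = 1.0 - 1e-9  # early stop threshold
    substeps: int = 10
    eps_pos: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_c <= 1.0 or not 0.0 <= self.p_m <= 1.0:
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if self.population_size < 1:
            raise ConfigurationError("population size must be >= 1")
        if self.partitions < 1:
            raise ConfigurationError("partition count must be >= 1")
        if self.max_iterations < 0:
            raise ConfigurationError("max_iterations must be >= 0")
        self.intervals  # validates the three intervals

    @property
    def intervals(self) -> ParamIntervals:
        return ParamIntervals(rate=self.rate_interval,
                              kinetic=self.kinetic_interval,
                              delay=self.delay_interval)

    def alphabet(self, n_genes: int) -> SymbolAlphabet:
        return SymbolAlphabet(arities=tuple(self.function_set), n_genes=n_genes,
                              include_constant=self.include_constant)

    @property
    def integrator(self) -> IntegratorConfig:
        return IntegratorConfig(substeps=self.substeps, eps_pos=self.eps_pos)

    @property
    def sigma_rate(self) -> float:
        lo, hi = self.rate_interval
        return self.sigma_fraction * (hi - lo)

    @property
    def sigma_kinetic(self) -> float:
        lo, hi = self.kinetic_interval
        return self.sigma_fraction * (hi - lo)


@dataclass
class Population:
    chromosomes: List[Chromosome]
    generation: int = 0

    def __len__(self) -> int:
        return len(self.chromosomes)


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

class FitnessEvaluator:
    """Precomputes delayed regulator tables for fast repeated evaluation.

    All regulator levels a candidate equation can reference are interpolated
    once onto the half-step RK4 stage grid for every lag in
    ``[0, delay_max]``; per candidate only the target gene's own trajectory
    is integrated.
    """

    def __init__(self, target: int, datasets: Sequence[TimeSeriesDataset],
                 integrator: IntegratorConfig = IntegratorConfig(),
                 delay_max: int = 3):
        if not datasets:
            raise ValueError("need at least one dataset")
        ref = datasets[0]
        for ds in datasets[1:]:
            if ds.n_genes != ref.n_genes or not np.allclose(ds.times, ref.times):
                raise ValueError("datasets must share gene set and time grid")
        if not 0 <= target < ref.n_genes:
            raise IndexError(f"target {target} out of range")
        self.target = target
        self.datasets = list(datasets)
        self.integrator = integrator
        self.delay_max = delay_max
        self.n_genes = ref.n_genes
        self.dt = ref.dt

        sub = integrator.substeps
        self.sub = sub
        self.n_steps = (ref.n_timepoints - 1) * sub
        n_half = 2 * self.n_steps + 1
        half_times = ref.times[0] + (ref.dt / sub / 2.0) * np.arange(n_half)
        n_rep = len(datasets)
        # D[rep, gene, tau, q]: observed level of `gene` at stage time q minus
        # tau sampling intervals (constant history before t0)
        D = np.empty((n_rep, self.n_genes, delay_max + 1, n_half))
        for r, ds in enumerate(datasets):
            for tau in range(delay_max + 1):
                tq = np.clip(half_times - tau * ds.dt, ds.times[0], ds.times[-1])
                for g in range(self.n_genes):
                    D[r, g, tau] = np.interp(tq, ds.times, ds.values[g])
        self.D = D
        self.observed = np.stack([ds.values[target] for ds in datasets])
        self.y0 = np.ascontiguousarray(self.observed[:, 0])

    def _term_arrays(self, term, n_half: int):
        """Split a term into the precomputable stage product and self factors."""
        G = np.full((self.D.shape[0], n_half), term.rate * term.constant_factor)
        p_self = 0.0
        sd_shift: List[int] = []
        sd_e: List[float] = []
        for j, e, tau in term.factors:
            if j == self.target:
                if tau == 0:
                    p_self += e
                else:
                    sd_shift.append(2 * tau * self.sub)
                    sd_e.append(e)
            else:
                G *= self.D[:, j, tau, :] ** e
        return (np.ascontiguousarray(G), p_self,
                np.array(sd_shift, dtype=np.int64), np.array(sd_e))

    def predict(self, eq: TDSSEquation) -> Tuple[np.ndarray, np.ndarray]:
        """Trajectories (n_rep, n_timepoints) plus per-replicate validity."""
        if eq.target_index != self.target:
            raise ValueError("equation target does not match evaluator target")
        for j in eq.regulators():
            if not 0 <= j < self.n_genes:
                raise IndexError(f"regulator index {j} outside dataset")
        n_half = 2 * self.n_steps + 1
        Ga, pa, sda_shift, sda_e = self._term_arrays(eq.production, n_half)
        Gb, pb, sdb_shift, sdb_e = self._term_arrays(eq.consumption, n_half)
        h = self.dt / self.sub
        Y, ok = rk4_decoupled_batch(self.y0, self.n_steps, h, self.sub,
                                    Ga, Gb, pa, pb,
                                    sda_shift, sda_e, sdb_shift, sdb_e,
                                    self.integrator.eps_pos)
        return Y[:, ::self.sub], ok.astype(bool)

    def sse(self, eq: TDSSEquation) -> float:
        pred, ok = self.predict(eq)
        if not ok.all() or not np.isfinite(pred).all():
            return float("inf")
        with np.errstate(over="ignore"):
            return float(((pred - self.observed) ** 2).sum())

    def __call__(self, chrom: Chromosome) -> float:
        eq = decode_chromosome(chrom, self.target)
        s = self.sse(eq)
        if not np.isfinite(s):
            return 0.0
        return 1.0 / (1.0 + s)


_EVALUATOR_CACHE: Dict[tuple, FitnessEvaluator] = {}


def get_evaluator(target: int, datasets: Sequence[TimeSeriesDataset],
                  cfg: EvolutionConfig) -> FitnessEvaluator:
    key = (target, tuple(id(ds) for ds in datasets), cfg.substeps, cfg.eps_pos,
           cfg.intervals.delay_max)
    ev = _EVALUATOR_CACHE.get(key)
    if ev is None:
        ev = FitnessEvaluator(target, datasets, cfg.integrator,
                              delay_max=cfg.intervals.delay_max)
        _EVALUATOR_CACHE[key] = ev
    return ev


def fitness(chrom: Chromosome, target: int,
            datasets: Sequence[TimeSeriesDataset],
            cfg: EvolutionConfig) -> float:
    """``1 / (1 + SSE)`` over all replicates and time points; 0 if invalid."""
    return get_evaluator(target, datasets, cfg)(chrom)


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------

def _default_intervals(gene: RGEPGene) -> ParamIntervals:
    return ParamIntervals(delay=(0, gene.delay_max))


def mutate_structure(gene: RGEPGene, strategy: str, rng: np.random.Generator,
                     intervals: Optional[ParamIntervals] = None) -> RGEPGene:
    """Structure-region mutation preserving head/tail legality.

    ``single_point`` redraws one position (head from F∪T, tail from T);
    ``single_gene`` replaces the whole gene by a fresh random one;
    ``all_variables`` replaces every expressed terminal symbol by another
    terminal, leaving the tree shape unchanged.
    """
    if intervals is None:
        intervals = _default_intervals(gene)
    ab = gene.alphabet
    if strategy == "single_point":
        out = gene.copy()
        L = len(gene)
        pos = int(rng.integers(L))
        if pos < gene.head_length:
            pool = ab.all_symbols
        else:
            pool = ab.terminal_symbols
        new_sym = pool[int(rng.integers(len(pool)))]
        syms = list(out.head + out.tail)
        syms[pos] = new_sym
        h = gene.head_length
        return replace(out, head=tuple(syms[:h]), tail=tuple(syms[h:]))
    if strategy == "single_gene":
        return random_gene(ab, gene.head_length, intervals, rng)
    if strategy == "all_variables":
        out = gene.copy()
        syms = list(out.head + out.tail)
        terms = ab.terminal_symbols
        for pos in range(expressed_length(gene)):
            s = syms[pos]
            if ab.is_function(s):
                continue
            if len(terms) > 1:
                others = [t for t in terms if t != s]
                syms[pos] = others[int(rng.integers(len(others)))]
        h = gene.head_length
        return replace(out, head=tuple(syms[:h]), tail=tuple(syms[h:]))
    raise ConfigurationError(f"unknown structure mutation strategy {strategy!r}")


def mutate_real(values: np.ndarray, interval: Tuple[float, float], p_m: float,
                sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Per-slot Gaussian mutation ``X' = X + delta``, clipped to the interval."""
    values = np.asarray(values, dtype=float)
    mask = rng.random(values.shape) < p_m
    delta = rng.normal(0.0, sigma, size=values.shape) if sigma > 0 else 0.0
    mutated = np.clip(values + delta, interval[0], interval[1])
    return np.where(mask, mutated, values)


def mutate_binary(bits: np.ndarray, p_m: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Invert each bit independently with probability ``p_m``."""
    bits = np.asarray(bits, dtype=np.uint8)
    mask = rng.random(bits.shape) < p_m
    return np.where(mask, 1 - bits, bits).astype(np.uint8)


def mutate_chromosome(chrom: Chromosome, cfg: EvolutionConfig,
                      rng: np.random.Generator,
                      generation: int = 0) -> Chromosome:
    """Apply all three mutation kinds to one chromosome.

    With probability ``p_m`` one of the three structure strategies (drawn
    uniformly) is applied to one randomly chosen gene; real and binary
    regions are mutated per-slot with probability ``p_m`` each.
    """
    intervals = cfg.intervals
    genes = [chrom.gene1.copy(), chrom.gene2.copy()]
    if rng.random() < cfg.p_m:
        strat = STRUCTURE_MUTATIONS[int(rng.integers(len(STRUCTURE_MUTATIONS)))]
        gi = int(rng.integers(2))
        genes[gi] = mutate_structure(genes[gi], strat, rng, intervals)
    decay = cfg.sigma_decay ** generation
    for gi in (0, 1):
        g = genes[gi]
        rate = mutate_real(np.array([g.rate_constant]), intervals.rate,
                           cfg.p_m, cfg.sigma_rate * decay, rng)
        ks = mutate_real(g.kinetic_orders, intervals.kinetic,
                         cfg.p_m, cfg.sigma_kinetic * decay, rng)
        bits = mutate_binary(g.delay_bits, cfg.p_m, rng)
        genes[gi] = replace(g, rate_constant=float(rate[0]), kinetic_orders=ks,
                            delay_bits=bits)
    return Chromosome(genes[0], genes[1])


# ---------------------------------------------------------------------------
# crossover
# ---------------------------------------------------------------------------

def _check_compatible(x: Chromosome, y: Chromosome) -> None:
    if (x.gene1.alphabet != y.gene1.alphabet
            or x.gene1.head_length != y.gene1.head_length
            or x.gene1.delay_max != y.gene1.delay_max):
        raise IncompatibleParentsError("parents must share alphabet, head "
                                       "length and delay coding")


def crossover_structure(x: Chromosome, y: Chromosome, strategy: str,
                        rng: np.random.Generator) -> Tuple[Chromosome, Chromosome]:
    """Structure-region crossover.

    ``single_point``: a position in the concatenated symbol region (gene1
    then gene2) is drawn and all symbols after it are exchanged; positions
    align head-to-head and tail-to-tail so legality is preserved.
    ``single_gene``: one randomly chosen gene of each parent is swapped
    whole, together with its parameter slots.
    """
    _check_compatible(x, y)
    cx, cy = x.copy(), y.copy()
    cx.fitness = cy.fitness = None
    cx.partition_id = cy.partition_id = None
    if strategy == "single_point":
        L = len(x.gene1)
        point = int(rng.integers(2 * L))
        sx = list(cx.gene1.symbols + cx.gene2.symbols)
        sy = list(cy.gene1.symbols + cy.gene2.symbols)
        for q in range(point + 1, 2 * L):
            sx[q], sy[q] = sy[q], sx[q]
        h = x.gene1.head_length
        cx.gene1 = replace(cx.gene1, head=tuple(sx[:h]), tail=tuple(sx[h:L]))
        cx.gene2 = replace(cx.gene2, head=tuple(sx[L:L + h]), tail=tuple(sx[L + h:]))
        cy.gene1 = replace(cy.gene1, head=tuple(sy[:h]), tail=tuple(sy[h:L]))
        cy.gene2 = replace(cy.gene2, head=tuple(sy[L:L + h]), tail=tuple(sy[L + h:]))
        return cx, cy
    if strategy == "single_gene":
        gi = int(rng.integers(2))
        gj = int(rng.integers(2))
        gx = [cx.gene1, cx.gene2]
        gy = [cy.gene1, cy.gene2]
        gx[gi], gy[gj] = gy[gj], gx[gi]
        return (Chromosome(gx[0], gx[1]), Chromosome(gy[0], gy[1]))
    raise ConfigurationError(f"unknown structure crossover strategy {strategy!r}")


def crossover_real(x: np.ndarray, y: np.ndarray, gamma: float,
                   interval: Optional[Tuple[float, float]] = None
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Arithmetic crossover ``X' = X + gamma (X-Y)``, ``Y' = Y - gamma (X-Y)``.

    Before clipping the slot-wise sum ``X' + Y'`` equals ``X + Y``: the
    identity is algebraically exact (verifiable by running this function on
    exact-rational inputs); in float arithmetic it holds to rounding error.
    Pass ``interval=None`` to skip clipping.  Exact (object-dtype) inputs
    are processed without coercion.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.dtype != object:
        x = x.astype(float)
    if y.dtype != object:
        y = y.astype(float)
    if x.shape != y.shape:
        raise IncompatibleParentsError("real regions differ in length")
    d = gamma * (x - y)
    xo, yo = x + d, y - d
    if interval is not None:
        xo = np.clip(xo, interval[0], interval[1])
        yo = np.clip(yo, interval[0], interval[1])
    return xo, yo


def gamma_schedule(t: int, gamma0: float = 1.0) -> float:
    """Geometric decay ``gamma0 * 0.99**t``: wide moves early, small late."""
    if t < 0:
        raise ConfigurationError("iteration index must be >= 0")
    return gamma0 * 0.99 ** t


def crossover_binary(x: np.ndarray, y: np.ndarray, strategy: str,
                     rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Bit-region crossover on equal-length flat bit strings.

    ``single_point``: bits strictly before a random point are exchanged.
    ``two_point``: bits strictly between two random points are exchanged.
    """
    x = np.asarray(x, dtype=np.uint8).ravel().copy()
    y = np.asarray(y, dtype=np.uint8).ravel().copy()
    if x.shape != y.shape:
        raise IncompatibleParentsError("bit regions differ in length")
    n = len(x)
    if strategy == "single_point":
        p = int(rng.integers(n))
        x[:p], y[:p] = y[:p].copy(), x[:p].copy()
        return x, y
    if strategy == "two_point":
        p1 = int(rng.integers(n))
        p2 = int(rng.integers(n))
        lo, hi = min(p1, p2), max(p1, p2)
        x[lo + 1:hi], y[lo + 1:hi] = y[lo + 1:hi].copy(), x[lo + 1:hi].copy()
        return x, y
    raise ConfigurationError(f"unknown binary crossover strategy {strategy!r}")


def _real_regions(c: Chromosome):
    rates = np.array([c.gene1.rate_constant, c.gene2.rate_constant])
    ks = np.concatenate([c.gene1.kinetic_orders, c.gene2.kinetic_orders])
    return rates, ks


def _set_real_regions(c: Chromosome, rates: np.ndarray, ks: np.ndarray) -> Chromosome:
    L = len(c.gene1)
    g1 = replace(c.gene1, rate_constant=float(rates[0]),
                 kinetic_orders=ks[:L].copy())
    g2 = replace(c.gene2, rate_constant=float(rates[1]),
                 kinetic_orders=ks[L:].copy())
    return Chromosome(g1, g2)


def _bit_region(c: Chromosome) -> np.ndarray:
    return np.concatenate([c.gene1.delay_bits.ravel(),
                           c.gene2.delay_bits.ravel()])


def _set_bit_region(c: Chromosome, bits: np.ndarray) -> Chromosome:
    shape = c.gene1.delay_bits.shape
    n = shape[0] * shape[1]
    g1 = replace(c.gene1, delay_bits=bits[:n].reshape(shape).astype(np.uint8))
    g2 = replace(c.gene2, delay_bits=bits[n:].reshape(shape).astype(np.uint8))
    return Chromosome(g1, g2)


def crossover_chromosomes(x: Chromosome, y: Chromosome, cfg: EvolutionConfig,
                          generation: int,
                          rng: np.random.Generator) -> Tuple[Chromosome, Chromosome]:
    """All three crossover kinds applied to one parent pair.

    Structure strategy and binary strategy are drawn uniformly from their
    menus; the real regions use the arithmetic crossover with the
    iteration-dependent gamma.
    """
    _check_compatible(x, y)
    strat = STRUCTURE_CROSSOVERS[int(rng.integers(len(STRUCTURE_CROSSOVERS)))]
    cx, cy = crossover_structure(x, y, strat, rng)

    gamma = gamma_schedule(generation, cfg.gamma0)
    rx, kx = _real_regions(cx)
    ry, ky = _real_regions(cy)
    rx, ry = crossover_real(rx, ry, gamma, cfg.rate_interval)
    kx, ky = crossover_real(kx, ky, gamma, cfg.kinetic_interval)
    cx = _set_real_regions(cx, rx, kx)
    cy = _set_real_regions(cy, ry, ky)

    bstrat = BINARY_CROSSOVERS[int(rng.integers(len(BINARY_CROSSOVERS)))]
    bx, by = crossover_binary(_bit_region(cx), _bit_region(cy), bstrat, rng)
    return _set_bit_region(cx, bx), _set_bit_region(cy, by)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def roulette_select(population: Sequence[Chromosome],
                    fitnesses: Sequence[float], sum_f: float, count: int,
                    rng: np.random.Generator) -> List[Chromosome]:
    """Fitness-proportional sampling with replacement.

    Falls back to uniform selection (with a log message) when the total
    fitness is zero.
    """
    f = np.asarray(fitnesses, dtype=float)
    if len(population) != len(f):
        raise ValueError("population and fitnesses differ in length")
    if (f < 0).any():
        raise ValueError("fitnesses must be nonnegative")
    if sum_f <= 0:
        logger.warning("total fitness is zero; falling back to uniform selection")
        idx = rng.integers(0, len(population), size=count)
    else:
        cum = np.cumsum(f)
        u = rng.random(count) * sum_f
        idx = np.minimum(np.searchsorted(cum, u, side="right"), len(f) - 1)
    return [population[int(i)] for i in idx]
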