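"""Partitioned map/reduce-style generation loop.

Each generation, fitness of every chromosome is computed independently
(map; parallelizable across workers with results independent of worker
count), each chromosome draws a random partition id in ``[0, k)``, and the
chromosomes sharing a partition id reproduce among themselves (reduce):
roulette selection, the three-region crossover and mutation.  Offspring of
all partitions are merged to form the next generation, so population size
is conserved.  The distributed file-system plumbing of a cluster deployment
is replaced by an in-process pool; the key/value contract is kept.

Randomness is drawn from substreams derived deterministically from the
master seed by (phase, generation, partition), so results are reproducible
regardless of scheduling or worker count.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .evolution import (
    EvolutionConfig,
    FitnessEvaluator,
    crossover_chromosomes,
    get_evaluator,
    mutate_chromosome,
    roulette_select,
)
from .simulation import TimeSeriesDataset
from .tdss_core import Chromosome, random_chromosome

__all__ = ["MapRecord", "GenerationStats", "map_phase", "reduce_phase",
           "serial_generation", "evolve"]

logger = logging.getLogger(__name__)

# substream tags: keep the phases' random streams disjoint
_TAG_INIT = 0
_TAG_MAP = 1
_TAG_REDUCE = 2


@dataclass
class MapRecord:
    """Key/value pair emitted by the map phase for one chromosome."""

    key: int  # partition id in [0, k)
    chromosome: Chromosome
    fitness: float
    sum_f: float  # population-wide fitness total, identical on all records


@dataclass
class GenerationStats:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_so_far: float


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + list(tags)))


def _eval_chunk(chroms: List[Chromosome], target: int,
                datasets: Sequence[TimeSeriesDataset],
                integrator, delay_max: int) -> List[float]:
    ev = FitnessEvaluator(target, datasets, integrator, delay_max=delay_max)
    return [ev(c) for c in chroms]


def map_phase(population: Sequence[Chromosome], target: int,
              datasets: Sequence[TimeSeriesDataset], cfg: EvolutionConfig,
              rng: np.random.Generator, workers: int = 1) -> List[MapRecord]:
    """Compute fitness per chromosome, draw partition ids, attach sum_f.

    Fitness is a pure per-chromosome computation, so the records are
    identical for any worker count.
    """
    pop = list(population)
    if workers > 1 and len(pop) > 1:
        from joblib import Parallel, delayed

        chunks = np.array_split(np.arange(len(pop)), workers)
        results = Parallel(n_jobs=workers)(
            delayed(_eval_chunk)([pop[i] for i in idx], target, datasets,
                                 cfg.integrator, cfg.intervals.delay_max)
            for idx in chunks if len(idx))
        fits = [f for chunk in results for f in chunk]
    else:
        ev = get_evaluator(target, datasets, cfg)
        fits = [ev(c) for c in pop]
    sum_f = float(np.sum(fits))
    keys = rng.integers(0, cfg.partitions, size=len(pop))
    records = []
    for chrom, f, key in zip(pop, fits, keys):
        chrom.fitness = float(f)
        chrom.partition_id = int(key)
        records.append(MapRecord(key=int(key), chromosome=chrom,
                                 fitness=float(f), sum_f=sum_f))
    return records


def _reproduce_group(members: List[Chromosome], fits: List[float],
                     cfg: EvolutionConfig, generation: int,
                     rng: np.random.Generator) -> List[Chromosome]:
    """Produce exactly ``len(members)`` offspring from one partition."""
    quota = len(members)
    group_sum = float(np.sum(fits))
    offspring: List[Chromosome] = []
    while len(offspring) < quota:
        pa, pb = roulette_select(members, fits, group_sum, 2, rng)
        if rng.random() < cfg.p_c:
            ca, cb = crossover_chromosomes(pa, pb, cfg, generation, rng)
        else:
            ca, cb = pa.copy(), pb.copy()
        offspring.append(mutate_chromosome(ca, cfg, rng, generation))
        if len(offspring) < quota:
            offspring.append(mutate_chromosome(cb, cfg, rng, generation))
    return offspring


def reduce_phase(records: Sequence[MapRecord], cfg: EvolutionConfig,
                 generation: int,
                 seed: Optional[int] = None) -> List[Chromosome]:
    """Group records by partition id and reproduce within each group.

    Each partition gets its own random substream derived from
    (seed, generation, partition id), so the merged offspring do not depend
    on scheduling.  Selection uses fitness-proportional probabilities within
    the group.  Empty partitions contribute no offspring (their quota is
    zero by construction), so the offspring count equals the parent count.
    """
    if seed is None:
        seed = cfg.seed
    groups: Dict[int, List[MapRecord]] = {}
    for rec in records:
        groups.setdefault(rec.key, []).append(rec)
    offspring: List[Chromosome] = []
    for pid in sorted(groups):
        group = groups[pid]
        rng = _rng(seed, _TAG_REDUCE, generation, pid)
        offspring.extend(_reproduce_group([r.chromosome for r in group],
                                          [r.fitness for r in group],
                                          cfg, generation, rng))
    if len(offspring) != len(records):
        raise AssertionError("offspring count must equal population size")
    return offspring


def serial_generation(population: Sequence[Chromosome], fitnesses: Sequence[float],
                      cfg: EvolutionConfig, generation: int,
                      seed: Optional[int] = None) -> List[Chromosome]:
    """Plain (unpartitioned) serial GA generation over the whole population.

    Reference path for the k=1 equivalence property: with one partition the
    map/reduce loop must reproduce this exactly under the same seed.
    """
    if seed is None:
        seed = cfg.seed
    rng = _rng(seed, _TAG_REDUCE, generation, 0)
    members = list(population)
    fits = [float(f) for f in fitnesses]
    total = float(np.sum(fits))
    out: List[Chromosome] = []
    while len(out) < len(members):
        pa, pb = roulette_select(members, fits, total, 2, rng)
        if rng.random() < cfg.p_c:
            ca, cb = crossover_chromosomes(pa, pb, cfg, generation, rng)
        else:
            ca, cb = pa.copy(), pb.copy()
        out.append(mutate_chromosome(ca, cfg, rng, generation))
        if len(out) < len(members):
            out.append(mutate_chromosome(cb, cfg, rng, generation))
    return out


def _checkpoint(path: str, generation: int, records: Sequence[MapRecord]) -> None:
    os.makedirs(path, exist_ok=True)
    fname = os.path.join(path, f"gen_{generation:05d}.txt")
    with open(fname, "w") as fh:
        for rec in records:
            fh.write(f"{rec.fitness!r}\t{rec.chromosome.to_text()}\n")


def evolve(target: int, datasets: Sequence[TimeSeriesDataset],
           cfg: EvolutionConfig, workers: int = 1,
           checkpoint_dir: Optional[str] = None
           ) -> Tuple[Chromosome, List[GenerationStats]]:
    """Run the partitioned evolutionary loop for one target gene.

    Returns the elitist best chromosome (fitness attached) and the
    per-generation statistics trace.  ``max_iterations = 0`` evaluates only
    the initial random population.
    """
    n_genes = datasets[0].n_genes
    alphabet = cfg.alphabet(n_genes)
    intervals = cfg.intervals
    init_rng = _rng(cfg.seed, _TAG_INIT)
    population = [random_chromosome(alphabet, cfg.head_length, intervals, init_rng)
                  for _ in range(cfg.population_size)]

    best: Optional[Chromosome] = None
    best_f = -np.inf
    trace: List[GenerationStats] = []
    for gen in range(cfg.max_iterations + 1):
        map_rng = _rng(cfg.seed, _TAG_MAP, gen)
        records = map_phase(population, target, datasets, cfg, map_rng,
                            workers=workers)
        fits = np.array([r.fitness for r in records])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_f:
            best_f = float(fits[gen_best])
            best = records[gen_best].chromosome.copy()
        trace.append(GenerationStats(generation=gen,
                                     best_fitness=float(fits[gen_best]),
                                     mean_fitness=float(fits.mean()),
                                     best_so_far=best_f))
        logger.info("gen %d: best=%.6g mean=%.6g best_so_far=%.6g",
                    gen, fits[gen_best], fits.mean(), best_f)
        logger.debug("gen %d best chromosome: %s", gen, best.to_text())
        if checkpoint_dir:
            _checkpoint(checkpoint_dir, gen, records)
        if best_f >= cfg.target_fitness or gen == cfg.max_iterations:
            break
        offspring = reduce_phase(records, cfg, gen, cfg.seed)
        if cfg.elitism:
            offspring[0] = best.copy()  # elite survives unmodified
        population = offspring

    assert best is not None
    best.fitness = best_f
    return best, trace
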