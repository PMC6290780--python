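"""Per-gene decomposition driver and network assembly.

Each gene's equation is fitted independently against the observed
trajectories of all genes (decomposition strategy); the fitted equations
are then read off into a directed edge set, each edge labeled instantaneous
(lag 0) or time-delayed (lag > 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from .evolution import EvolutionConfig
from .parallel_engine import GenerationStats, evolve
from .simulation import TimeSeriesDataset
from .tdss_core import Chromosome, TDSSEquation, decode_chromosome

__all__ = ["Edge", "EdgeSet", "GeneResult", "extract_edges", "infer_network"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Edge:
    """Directed regulatory edge regulator -> target (0-based indices)."""

    regulator: int
    target: int
    role: str = "production"  # production | consumption
    exponent: float = 0.0
    delay: int = 0

    @property
    def delay_class(self) -> str:
        return "delayed" if self.delay > 0 else "instantaneous"


class EdgeSet:
    """Set of directed edges, unique per (regulator, target) pair.

    Merging keeps the representative with the largest exponent magnitude.
    """

    def __init__(self, edges: Iterable[Edge] = ()):
        self._edges: Dict[Tuple[int, int], Edge] = {}
        for e in edges:
            self.add(e)

    def add(self, edge: Edge) -> None:
        key = (edge.regulator, edge.target)
        cur = self._edges.get(key)
        if cur is None or abs(edge.exponent) > abs(cur.exponent):
            self._edges[key] = edge

    def update(self, other: "EdgeSet") -> None:
        for e in other:
            self.add(e)

    def pairs(self) -> set:
        return set(self._edges.keys())

    def get(self, regulator: int, target: int) -> Optional[Edge]:
        return self._edges.get((regulator, target))

    def __iter__(self) -> Iterator[Edge]:
        return iter(sorted(self._edges.values(),
                           key=lambda e: (e.target, e.regulator)))

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, pair: Tuple[int, int]) -> bool:
        return pair in self._edges

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EdgeSet):
            return NotImplemented
        return self._edges == other._edges


@dataclass
class GeneResult:
    """Outcome of fitting one target gene."""

    target: int
    chromosome: Optional[Chromosome]
    equation: Optional[TDSSEquation]
    fitness: float
    trace: List[GenerationStats]
    error: Optional[str] = None


def extract_edges(eq: TDSSEquation, eps: float = 0.05) -> EdgeSet:
    """Read regulatory edges off a fitted equation.

    Every factor (regulator, exponent, lag) in either term with
    ``|exponent| >= eps`` yields an edge to the target; constant-terminal
    factors carry no regulator and are ignored; duplicate pairs keep the
    largest-magnitude exponent.
    """
    if eps < 0:
        raise ValueError("exponent threshold must be >= 0")
    out = EdgeSet()
    for role, term in (("production", eq.production),
                       ("consumption", eq.consumption)):
        for j, e, tau in term.factors:
            if abs(e) >= eps:
                out.add(Edge(regulator=j, target=eq.target_index, role=role,
                             exponent=e, delay=tau))
    return out


def infer_network(datasets: Sequence[TimeSeriesDataset], cfg: EvolutionConfig,
                  workers: int = 1, eps: float = 0.05,
                  genes: Optional[Sequence[int]] = None
                  ) -> Tuple[EdgeSet, List[GeneResult]]:
    """Fit every target gene independently and assemble the edge set.

    Per-gene seeds are derived as ``cfg.seed + gene index`` so results for
    one gene are independent of which other genes are run.  A failure for
    one gene is recorded in its :class:`GeneResult` and skipped.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    n_genes = datasets[0].n_genes
    targets = list(genes) if genes is not None else list(range(n_genes))
    edges = EdgeSet()
    results: List[GeneResult] = []
    for i in targets:
        gene_cfg = replace(cfg, seed=cfg.seed + i)
        try:
            best, trace = evolve(i, datasets, gene_cfg, workers=workers)
            eq = decode_chromosome(best, i)
            edges.update(extract_edges(eq, eps))
            results.append(GeneResult(target=i, chromosome=best, equation=eq,
                                      fitness=float(best.fitness), trace=trace))
            logger.info("gene %d fitted: fitness=%.6g", i, best.fitness)
        except Exception as exc:  # pragma: no cover - defensive
            logger.exception("inference failed for gene %d", i)
            results.append(GeneResult(target=i, chromosome=None, equation=None,
                                      fitness=0.0, trace=[], error=str(exc)))
    return edges, results
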