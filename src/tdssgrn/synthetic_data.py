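"""Ground-truth network and dataset generator for benchmarking.

Samples directed networks with exact edge and delayed-edge counts on a
preferential-attachment (out-hub) topology, parameterizes them as
time-delayed S-systems, and simulates multi-replicate time series.  Serves
as a self-contained stand-in for external benchmark generators so the whole
pipeline is testable offline: truth edges get exponents bounded away from
zero so they are recoverable in principle, and every gene receives a
(self-loop) degradation term for bounded dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .inference import Edge, EdgeSet
from .simulation import (
    IntegratorConfig,
    SimulationError,
    TimeSeriesDataset,
    simulate_network,
)
from .tdss_core import ConfigurationError, TDSSEquation, TDSSTerm

__all__ = ["NetworkSpec", "generate_network", "generate_datasets",
           "generate_benchmark"]


@dataclass(frozen=True)
class NetworkSpec:
    """Shape of a synthetic time-delayed regulatory network."""

    n_genes: int
    n_edges: int
    n_delayed_edges: int
    delay_max: int = 3
    exponent_range: Tuple[float, float] = (0.1, 1.0)  # >= 2x default edge threshold
    rate_range: Tuple[float, float] = (0.5, 1.5)
    self_degradation_range: Tuple[float, float] = (0.5, 1.0)

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ConfigurationError("need at least 2 genes")
        if not 0 <= self.n_edges <= self.n_genes * (self.n_genes - 1):
            raise ConfigurationError(
                f"{self.n_edges} edges infeasible for {self.n_genes} genes "
                "without self-loops")
        if not 0 <= self.n_delayed_edges <= self.n_edges:
            raise ConfigurationError("delayed edges cannot exceed edge count")
        if self.delay_max < 1 and self.n_delayed_edges > 0:
            raise ConfigurationError("delayed edges require delay_max >= 1")


def _sample_topology(spec: NetworkSpec,
                     rng: np.random.Generator) -> List[Tuple[int, int]]:
    """Directed edges without self-loops; regulators chosen with probability
    proportional to (current out-degree + 1), producing out-hub structure."""
    n = spec.n_genes
    edges: set = set()
    outdeg = np.zeros(n)
    while len(edges) < spec.n_edges:
        w = outdeg + 1.0
        j = int(rng.choice(n, p=w / w.sum()))
        i = int(rng.integers(n))
        if i == j or (j, i) in edges:
            continue
        edges.add((j, i))
        outdeg[j] += 1
    return sorted(edges)


def generate_network(spec: NetworkSpec, rng: np.random.Generator
                     ) -> Tuple[List[TDSSEquation], EdgeSet]:
    """Sample equations and the exact truth edge set for a spec.

    Each sampled edge is assigned to the production or consumption term of
    its target with equal probability; exactly ``n_delayed_edges`` edges get
    a lag drawn uniformly from {1..delay_max}, the rest are instantaneous.
    Kinetic orders of truth edges are drawn within ``exponent_range`` (floor
    well above the default extraction threshold).  Every gene additionally
    gets an instantaneous self-degradation factor in its consumption term;
    self-loops are not part of the truth edge set.
    """
    edge_list = _sample_topology(spec, rng)
    delayed_idx = set(
        rng.choice(len(edge_list), size=spec.n_delayed_edges, replace=False)
        .tolist()) if spec.n_delayed_edges else set()

    truth = EdgeSet()
    prod_factors: List[List[Tuple[int, float, int]]] = [[] for _ in range(spec.n_genes)]
    cons_factors: List[List[Tuple[int, float, int]]] = [[] for _ in range(spec.n_genes)]
    for idx, (j, i) in enumerate(edge_list):
        e = float(rng.uniform(*spec.exponent_range))
        tau = int(rng.integers(1, spec.delay_max + 1)) if idx in delayed_idx else 0
        role = "production" if rng.random() < 0.5 else "consumption"
        (prod_factors if role == "production" else cons_factors)[i].append((j, e, tau))
        truth.add(Edge(regulator=j, target=i, role=role, exponent=e, delay=tau))

    equations = []
    for i in range(spec.n_genes):
        alpha = float(rng.uniform(*spec.rate_range))
        beta = float(rng.uniform(*spec.rate_range))
        self_h = float(rng.uniform(*spec.self_degradation_range))
        cons = cons_factors[i] + [(i, self_h, 0)]
        equations.append(TDSSEquation(
            target_index=i,
            production=TDSSTerm(rate=alpha, factors=tuple(prod_factors[i])),
            consumption=TDSSTerm(rate=beta, factors=tuple(cons)),
        ))
    return equations, truth


def generate_datasets(net: Sequence[TDSSEquation], n_replicates: int,
                      n_timepoints: int, t_span: Tuple[float, float],
                      noise_sd: float, rng: np.random.Generator,
                      cfg: IntegratorConfig = IntegratorConfig(),
                      max_retries: int = 5,
                      init_range: Tuple[float, float] = (0.5, 1.5)
                      ) -> List[TimeSeriesDataset]:
    """Simulate replicates with random positive initial conditions.

    Multiplicative log-normal noise of scale ``noise_sd`` is applied to the
    noise-free trajectories (0 = noise-free).  Replicates whose simulation
    blows up are retried with fresh initial conditions a bounded number of
    times before erroring out.
    """
    if n_timepoints < 2:
        raise ValueError("need at least two time points")
    times = np.linspace(t_span[0], t_span[1], n_timepoints)
    n = len(net)
    datasets = []
    for rep in range(n_replicates):
        last_err: Exception = RuntimeError("unreachable")
        for _ in range(max_retries):
            x0 = rng.uniform(init_range[0], init_range[1], size=n)
            try:
                ds = simulate_network(net, x0, times, cfg)
            except SimulationError as exc:
                last_err = exc
                continue
            if ds.values.max() > 1e6:  # finite but useless: treat as blow-up
                last_err = SimulationError("trajectory exceeded 1e6")
                continue
            break
        else:
            raise SimulationError(
                f"replicate {rep} failed after {max_retries} retries: {last_err}")
        values = ds.values
        if noise_sd > 0:
            values = values * np.exp(rng.normal(0.0, noise_sd, size=values.shape))
            values = np.maximum(values, cfg.eps_pos)
        datasets.append(TimeSeriesDataset(times=times, values=values,
                                          replicate_id=rep))
    return datasets


def generate_benchmark(spec: NetworkSpec, n_replicates: int = 10,
                       n_timepoints: int = 21,
                       t_span: Tuple[float, float] = (0.0, 20.0),
                       noise_sd: float = 0.0, seed: int = 0,
                       cfg: IntegratorConfig = IntegratorConfig()
                       ) -> Tuple[List[TDSSEquation], EdgeSet, List[TimeSeriesDataset]]:
    """Convenience wrapper: network plus replicate datasets from one seed."""
    rng = np.random.default_rng(seed)
    net, truth = generate_network(spec, rng)
    datasets = generate_datasets(net, n_replicates, n_timepoints, t_span,
                                 noise_sd, rng, cfg)
    return net, truth, datasets
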