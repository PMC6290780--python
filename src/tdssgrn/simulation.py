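"""Integration of time-delayed S-system dynamics.

Two integration modes are provided:

* :func:`simulate_network` — full delay system, method of steps, used to
  generate synthetic data;
* :func:`simulate_gene_decoupled` — a single target gene integrated against
  observed trajectories of all other genes, the workhorse of fitness
  evaluation under the per-gene decomposition strategy.

Both use fixed-step classical Runge–Kutta (RK4) with a configurable number
of substeps per sampling interval, states clamped at a small positivity
floor so power laws stay defined.  Delays are integer multiples of the
(uniform) sampling interval; history before the first sample is constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .tdss_core import TDSSEquation

__all__ = [
    "SimulationError",
    "TimeSeriesDataset",
    "IntegratorConfig",
    "delayed_value",
    "simulate_gene_decoupled",
    "simulate_network",
]


class SimulationError(RuntimeError):
    """Raised when a full-network integration produces a non-finite state."""


@dataclass
class TimeSeriesDataset:
    """One replicate: a uniform time grid and positive expression levels.

    ``values`` has shape (genes, time points).
    """

    times: np.ndarray
    values: np.ndarray
    replicate_id: int = 0
    gene_ids: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need a 1-D time grid with at least two points")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.times):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.times)} time points")
        steps = np.diff(self.times)
        if (steps <= 0).any():
            raise ValueError("time grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time grid must be uniform")
        if (self.values <= 0).any():
            raise ValueError("expression levels must be strictly positive")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class IntegratorConfig:
    substeps: int = 10
    eps_pos: float = 1e-6

    def __post_init__(self) -> None:
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")
        if self.eps_pos <= 0:
            raise ValueError("positivity floor must be > 0")


def delayed_value(ds: TimeSeriesDataset, gene: int, t: float, tau: int) -> float:
    """Level of ``gene`` at time ``t - tau*dt``, linearly interpolated.

    Times earlier than the first sample return the first sample (constant
    history).
    """
    if not 0 <= gene < ds.n_genes:
        raise IndexError(f"gene index {gene} out of range [0, {ds.n_genes})")
    tq = t - tau * ds.dt
    if tq <= ds.times[0]:
        return float(ds.values[gene, 0])
    # np.interp clamps at the right edge, which only matters for tau=0 at t_end
    return float(np.interp(tq, ds.times, ds.values[gene]))


def _hermite_lagged(levels: np.ndarray, derivs: np.ndarray, q: int,
                    h: float, floor: float) -> float:
    """Value of a stored fine-grid trajectory at half-index ``q``.

    Integer lags land either exactly on a fine node (even ``q``) or exactly
    midway between two nodes (odd ``q``); midpoints use the cubic Hermite
    formula with the stored node derivatives, keeping delayed lookups
    4th-order accurate.  ``q <= 0`` is the constant pre-t0 history.  The
    (non-monotone) Hermite midpoint is clamped at the positivity floor.
    """
    if q <= 0:
        return float(levels[0])
    if q % 2 == 0:
        return float(levels[q // 2])
    a, b = (q - 1) // 2, (q + 1) // 2
    v = float(0.5 * (levels[a] + levels[b]) + h / 8.0 * (derivs[a] - derivs[b]))
    return v if v > floor else floor


def simulate_gene_decoupled(eq: TDSSEquation, ds: TimeSeriesDataset,
                            cfg: IntegratorConfig = IntegratorConfig()) -> np.ndarray:
    """Integrate the target gene's equation against observed regulators.

    Regulator levels (genes other than the target) are read from the
    observed dataset via :func:`delayed_value`; the target's own level comes
    from the running integration (its own past via :func:`_hermite_lagged`
    on the fine grid, constant history before t0).  Starts at the observed
    level at t0.

    Returns the predicted trajectory of the target on ``ds.times``.  If the
    state becomes non-finite the returned array contains NaN from the point
    of failure on — callers treat any non-finite trajectory as invalid.
    """
    i = eq.target_index
    if not 0 <= i < ds.n_genes:
        raise IndexError(f"target index {i} out of range")
    sub = cfg.substeps
    dt = ds.dt
    h = dt / sub
    n_fine = (ds.n_timepoints - 1) * sub + 1
    t0 = float(ds.times[0])
    y_fine = np.full(n_fine, np.nan)
    f_fine = np.zeros(n_fine)  # stored node derivatives for Hermite midpoints
    y_fine[0] = ds.values[i, 0]

    factors = [(j, e, tau, role)
               for role, term in (("p", eq.production), ("c", eq.consumption))
               for j, e, tau in term.factors]
    a = eq.production.rate * eq.production.constant_factor
    b = eq.consumption.rate * eq.consumption.constant_factor

    def deriv(q: int, y: float) -> float:
        # q is the half-index of the stage time: t = t0 + q*h/2
        t = t0 + q * h / 2.0
        prod = a
        cons = b
        for j, e, tau, role in factors:
            if j == i:
                x = y if tau == 0 else _hermite_lagged(y_fine, f_fine,
                                                       q - 2 * tau * sub, h,
                                                       cfg.eps_pos)
            else:
                x = delayed_value(ds, j, t, tau)
            if role == "p":
                prod *= x ** e
            else:
                cons *= x ** e
        return prod - cons

    floor = cfg.eps_pos
    y = float(y_fine[0])
    for m in range(n_fine - 1):
        q = 2 * m
        try:
            k1 = deriv(q, y)
            f_fine[m] = k1
            k2 = deriv(q + 1, max(y + h / 2 * k1, floor))
            k3 = deriv(q + 1, max(y + h / 2 * k2, floor))
            k4 = deriv(q + 2, max(y + h * k3, floor))
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        except OverflowError:
            break  # remaining entries stay NaN -> trajectory flagged invalid
        if not np.isfinite(y):
            break
        y = max(y, floor)
        y_fine[m + 1] = y

    return y_fine[::sub].copy()


def simulate_network(net: Sequence[TDSSEquation], x0: np.ndarray,
                     times: np.ndarray,
                     cfg: IntegratorConfig = IntegratorConfig()) -> TimeSeriesDataset:
    """Method-of-steps integration of the full delay system.

    History is constant (equal to ``x0``) for t < t0.  Delayed lookups
    linearly interpolate the stored fine-grid past; instantaneous (tau=0)
    factors use the current RK4 stage state.
    """
    times = np.asarray(times, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    n = len(net)
    if x0.shape != (n,):
        raise ValueError("one initial level per equation required")
    if (x0 <= 0).any():
        raise ValueError("initial levels must be positive")
    steps = np.diff(times)
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
        raise ValueError("time grid must be uniform")
    for idx, eq in enumerate(net):
        if eq.target_index != idx:
            raise ValueError(f"equation {idx} has target_index {eq.target_index}")

    dt = float(steps[0])
    sub = cfg.substeps
    h = dt / sub
    n_fine = (len(times) - 1) * sub + 1
    fine_times = times[0] + h * np.arange(n_fine)
    Y = np.full((n, n_fine), np.nan)
    F = np.zeros((n, n_fine))  # node derivatives for Hermite midpoints
    Y[:, 0] = x0
    floor = cfg.eps_pos

    per_gene = []
    for eq in net:
        pf = eq.production.factors
        cf = eq.consumption.factors
        a = eq.production.rate * eq.production.constant_factor
        b = eq.consumption.rate * eq.consumption.constant_factor
        per_gene.append((a, pf, b, cf))

    def deriv(q: int, y: np.ndarray) -> np.ndarray:
        # q: half-index of the stage time on the fine grid
        out = np.empty(n)
        for i, (a, pf, b, cf) in enumerate(per_gene):
            prod = a
            for j, e, tau in pf:
                x = y[j] if tau == 0 else _hermite_lagged(Y[j], F[j],
                                                          q - 2 * tau * sub, h,
                                                          floor)
                prod *= x ** e
            cons = b
            for j, e, tau in cf:
                x = y[j] if tau == 0 else _hermite_lagged(Y[j], F[j],
                                                          q - 2 * tau * sub, h,
                                                          floor)
                cons *= x ** e
            out[i] = prod - cons
        return out

    y = x0.copy()
    # overflow surfaces as SimulationError below, not as a numpy warning
    with np.errstate(over="ignore", invalid="ignore"):
        for m in range(n_fine - 1):
            q = 2 * m
            try:
                k1 = deriv(q, y)
                F[:, m] = k1
                k2 = deriv(q + 1, np.maximum(y + h / 2 * k1, floor))
                k3 = deriv(q + 1, np.maximum(y + h / 2 * k2, floor))
                k4 = deriv(q + 2, np.maximum(y + h * k3, floor))
                y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            except OverflowError:
                raise SimulationError(
                    f"state overflowed at t = {fine_times[m + 1]:.6g}") from None
            if not np.isfinite(y).all():
                raise SimulationError(
                    f"state became non-finite at t = {fine_times[m + 1]:.6g}")
            y = np.maximum(y, floor)
            Y[:, m + 1] = y

    return TimeSeriesDataset(times=times, values=Y[:, ::sub].copy())
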