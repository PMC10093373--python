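"""Henry Gas Solubility Optimization (HGSO).

A physics-inspired population metaheuristic: search agents ("gases") are
partitioned into clusters that share a Henry coefficient H_j.  An annealing
temperature T(t) = exp(-t / max_iter) drives H_j down each iteration,
solubility S_ij = K * H_j * P_ij couples each agent's partial pressure to its
cluster, and positions move toward the cluster best and the solubility-scaled
global best.  A fraction of the worst agents (between C1 and C2 of the
population) is re-seeded uniformly every iteration to escape local optima.
Minimization convention throughout: lower fitness is better.

The hyperparameter-tuning glue (bounded search-space encoding and the
misclassification-rate fitness) lives here as well.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np

__all__ = ["HGSOConfig", "SearchBounds", "HGSOState", "HGSOResult",
           "initialize_population", "rank_and_select_best",
           "update_henry_coefficient", "update_solubility", "update_positions",
           "count_worst_agents", "reinitialize_worst", "hgso_minimize",
           "Dimension", "HyperparameterSpace", "default_hyperparameter_space",
           "misclassification_rate"]


@dataclasses.dataclass(frozen=True)
class HGSOConfig:
    population_size: int = 30
    n_clusters: int = 5
    max_iter: int = 100
    l1: float = 5e-2       # Henry-constant init scale
    l2: float = 100.0      # partial-pressure init scale
    l3: float = 1e-2       # cluster-constant init scale
    K: float = 1.0         # solubility constant
    alpha: float = 1.0     # influence of the global best
    beta: float = 1.0      # interaction strength in gamma
    epsilon: float = 0.05
    T_theta: float = 298.0
    c1: float = 0.1        # worst-agent fraction bounds
    c2: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.n_clusters < 1 or self.population_size % self.n_clusters:
            raise ValueError("n_clusters must divide population_size")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.c1 < self.c2:
            raise ValueError("c1 must be < c2")
        for name in ("l1", "l2", "l3", "K", "alpha", "beta", "epsilon",
                     "T_theta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclasses.dataclass(frozen=True)
class SearchBounds:
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.atleast_1d(np.asarray(self.lower, dtype=np.float64))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=np.float64))
        if lo.shape != hi.shape or not np.all(lo < hi):
            raise ValueError("bounds require lower < upper componentwise")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclasses.dataclass
class HGSOState:
    positions: np.ndarray          # (N, d)
    fitness: np.ndarray            # (N,)
    cluster_of: np.ndarray         # (N,) agent -> cluster index
    henry: np.ndarray              # (n_clusters,) H_j
    cluster_const: np.ndarray      # (n_clusters,) C_j
    pressure: np.ndarray           # (N,) P_ij
    solubility: np.ndarray         # (N,) S_ij


@dataclasses.dataclass
class HGSOResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray            # best-so-far fitness per iteration


def initialize_population(bounds: SearchBounds, config: HGSOConfig,
                          rng: np.random.Generator) -> HGSOState:
    """Uniform positions; per-cluster H_j and C_j, per-agent P_ij, all drawn
    as constant * U(0,1).  Agents in one cluster share H_j."""
    n, k = config.population_size, config.n_clusters
    r = rng.random((n, bounds.dim))
    positions = bounds.lower + r * (bounds.upper - bounds.lower)
    henry = config.l1 * rng.random(k)
    pressure = config.l2 * rng.random(n)
    cluster_const = config.l3 * rng.random(k)
    cluster_of = np.repeat(np.arange(k), n // k)
    return HGSOState(positions=positions, fitness=np.full(n, np.inf),
                     cluster_of=cluster_of, henry=henry,
                     cluster_const=cluster_const, pressure=pressure,
                     solubility=np.zeros(n))


def rank_and_select_best(state: HGSOState) -> tuple[np.ndarray, int]:
    """Argmin fitness per cluster and overall; ties go to the lowest agent
    index (argmin's convention)."""
    n_clusters = state.henry.size
    cluster_best = np.empty(n_clusters, dtype=int)
    for j in range(n_clusters):
        members = np.flatnonzero(state.cluster_of == j)
        cluster_best[j] = members[np.argmin(state.fitness[members])]
    return cluster_best, int(np.argmin(state.fitness))


def update_henry_coefficient(state: HGSOState, t: int, config: HGSOConfig
                             ) -> np.ndarray:
    """H_j <- H_j * exp(-C_j * (1/T(t) - 1/T_theta)), T(t) = exp(-t/max_iter).

    T(t) < 1 << T_theta makes the exponent negative, so H decays strictly
    whenever C_j > 0."""
    if not 1 <= t <= config.max_iter:
        raise ValueError("iteration t must be in [1, max_iter]")
    temperature = math.exp(-t / config.max_iter)
    state.henry = state.henry * np.exp(
        -state.cluster_const * (1.0 / temperature - 1.0 / config.T_theta))
    return state.henry


def update_solubility(state: HGSOState, config: HGSOConfig) -> np.ndarray:
    """S_ij = K * H_j * P_ij."""
    state.solubility = config.K * state.henry[state.cluster_of] * state.pressure
    return state.solubility


def update_positions(state: HGSOState, cluster_best_pos: np.ndarray,
                     global_best_pos: np.ndarray, global_best_fit: float,
                     config: HGSOConfig, rng: np.random.Generator
                     ) -> np.ndarray:
    """One position update for every agent.

    gamma_i = beta * exp(-(F_best + eps) / (F_i + eps));
    x_i <- x_i + f_i*r1*gamma_i*(x_cluster_best - x_i)
               + f_i*r2*alpha*(S_i * x_global_best - x_i)
    with a direction flag f_i in {+1,-1} resampled per agent and fresh
    r1, r2 ~ U(0,1) per agent.  Draw order: flags, r1, r2.
    """
    n = state.positions.shape[0]
    flags = np.where(rng.random(n) >= 0.5, 1.0, -1.0)[:, None]
    r1 = rng.random(n)[:, None]
    r2 = rng.random(n)[:, None]
    gamma = config.beta * np.exp(
        -(global_best_fit + config.epsilon)
        / (state.fitness + config.epsilon))[:, None]
    x = state.positions
    step = (flags * r1 * gamma * (cluster_best_pos - x)
            + flags * r2 * config.alpha
            * (state.solubility[:, None] * global_best_pos - x))
    return x + step


def count_worst_agents(n: int, config: HGSOConfig, rng: np.random.Generator
                       ) -> int:
    """Nw = round(N * (rand*(C2-C1) + C1)), round half to even, clamped to
    [1, N]."""
    raw = n * (rng.random() * (config.c2 - config.c1) + config.c1)
    # kill accumulated FP noise before the half-even rounding
    return int(np.clip(np.round(np.round(raw, 9)), 1, n))


def reinitialize_worst(state: HGSOState, n_worst: int, bounds: SearchBounds,
                       rng: np.random.Generator) -> np.ndarray:
    """Re-seed the n_worst highest-fitness agents uniformly in the bounds;
    returns the indices that moved."""
    n = state.positions.shape[0]
    if not 0 <= n_worst <= n:
        raise ValueError("n_worst must be in [0, N]")
    if n_worst == 0:
        return np.array([], dtype=int)
    worst = np.argsort(-state.fitness, kind="stable")[:n_worst]
    r = rng.random((n_worst, bounds.dim))
    state.positions[worst] = bounds.lower + r * (bounds.upper - bounds.lower)
    return worst


def hgso_minimize(objective: Callable[[np.ndarray], float],
                  bounds: SearchBounds, config: HGSOConfig) -> HGSOResult:
    """Run the full HGSO loop for max_iter iterations.

    Per iteration: update H and S, move all agents (clipped to bounds),
    re-evaluate, re-seed the worst agents, then refresh cluster/global bests.
    The returned history is the best-so-far fitness after each iteration and
    is monotone non-increasing by construction (elitist archive).
    """
    rng = np.random.default_rng(config.seed)
    state = initialize_population(bounds, config, rng)

    def evaluate(indices: np.ndarray) -> None:
        for i in indices:
            f = float(objective(state.positions[i]))
            if not math.isfinite(f):
                raise ValueError(
                    f"objective returned non-finite value {f!r} for agent {i} "
                    f"at position {state.positions[i]!r}")
            state.fitness[i] = f

    everyone = np.arange(config.population_size)
    evaluate(everyone)
    cluster_best_idx, global_best_idx = rank_and_select_best(state)
    best_pos = state.positions[global_best_idx].copy()
    best_fit = float(state.fitness[global_best_idx])

    history = np.empty(config.max_iter)
    for t in range(1, config.max_iter + 1):
        update_henry_coefficient(state, t, config)
        update_solubility(state, config)
        cluster_best_pos = state.positions[cluster_best_idx][state.cluster_of]
        state.positions = bounds.clip(update_positions(
            state, cluster_best_pos, best_pos, best_fit, config, rng))
        evaluate(everyone)
        n_worst = count_worst_agents(config.population_size, config, rng)
        moved = reinitialize_worst(state, n_worst, bounds, rng)
        evaluate(moved)
        cluster_best_idx, global_best_idx = rank_and_select_best(state)
        if state.fitness[global_best_idx] < best_fit:
            best_fit = float(state.fitness[global_best_idx])
            best_pos = state.positions[global_best_idx].copy()
        history[t - 1] = best_fit
    return HGSOResult(best_position=best_pos, best_fitness=best_fit,
                      history=history)


# ---------------------------------------------------------------------------
# hyperparameter search space


@dataclasses.dataclass(frozen=True)
class Dimension:
    """One bounded search dimension.

    kind 'continuous': value in [low, high]; log10-scaled if log is set.
    kind 'integer':    integer in [low, high], nearest-integer decode.
    """

    name: str
    kind: str
    low: float
    high: float
    log: bool = False

    def __post_init__(self):
        if self.kind not in ("continuous", "integer"):
            raise ValueError("kind must be 'continuous' or 'integer'")
        if self.low >= self.high:
            raise ValueError("low must be < high")
        if self.log and self.low <= 0:
            raise ValueError("log scale requires positive bounds")

    @property
    def bounds(self) -> tuple[float, float]:
        if self.log:
            return math.log10(self.low), math.log10(self.high)
        return float(self.low), float(self.high)

    def decode(self, x: float) -> float | int:
        lo, hi = self.bounds
        if not lo - 1e-12 <= x <= hi + 1e-12:
            raise ValueError(f"position {x} outside bounds of {self.name}")
        v = 10.0 ** x if self.log else x
        if self.kind == "integer":
            return int(np.clip(np.round(v), self.low, self.high))
        return float(np.clip(v, self.low, self.high))

    def encode(self, value: float) -> float:
        return math.log10(value) if self.log else float(value)


class HyperparameterSpace:
    """Named bounded dimensions with encode/decode to HGSO position vectors."""

    def __init__(self, dimensions: Sequence[Dimension]):
        if not dimensions:
            raise ValueError("need at least one dimension")
        self.dimensions = list(dimensions)

    @property
    def bounds(self) -> SearchBounds:
        lohi = np.array([d.bounds for d in self.dimensions])
        return SearchBounds(lower=lohi[:, 0], upper=lohi[:, 1])

    def decode(self, position: np.ndarray) -> dict[str, float | int]:
        position = np.asarray(position, dtype=np.float64)
        if position.shape != (len(self.dimensions),):
            raise ValueError("position length must match dimension count")
        return {d.name: d.decode(x) for d, x in zip(self.dimensions, position)}

    def encode(self, settings: dict[str, float]) -> np.ndarray:
        return np.array([d.encode(settings[d.name]) for d in self.dimensions])


def default_hyperparameter_space() -> HyperparameterSpace:
    """Tuned set for the feature extractor: learning rate (log), batch size,
    epochs, dropout.  Spans the reference settings (0.01, 5, 50, 0.5)."""
    return HyperparameterSpace([
        Dimension("lr0", "continuous", 1e-4, 1e-1, log=True),
        Dimension("batch_size", "integer", 2, 64),
        Dimension("epochs", "integer", 5, 50),
        Dimension("dropout", "continuous", 0.0, 0.7),
    ])


def misclassification_rate(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Percentage of misclassified samples: 100 * wrong / total."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("label arrays must be non-empty and equal length")
    return 100.0 * float(np.mean(y_true != y_pred))
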