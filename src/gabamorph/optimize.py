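"""NSGA-II over the four treatment variables with an ideal-point fitness.

The trained trait surrogate serves as the objective oracle: every
chromosome (cultivar code, stress code, GABA dose in [0, 40] mM, day in
[0, 45]) is decoded to a predicted trait vector, and all five traits
are maximized.  Survival is the standard elitist scheme (non-dominated
fronts, then crowding distance, on parents + offspring).  Mating
selection is roulette-wheel on the scalar score 1 / (1 + F), where

    F = sqrt( sum_t (Y_t - ideal_t)^2 )

is the Euclidean distance of the predicted traits to the ideal point
(the per-trait maxima, taken from the training data by default).  F
also picks the single reported recommendation from the final front.
The individual with the lowest F is always retained, so the best-F
trajectory is non-increasing across generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import OptimizationError, ParameterError, SelectionError
from .synthetic import TRAITS

N_GENES = 4  # cultivar, stress, gaba, day


@dataclass
class NSGAConfig:
    """Genetic-algorithm settings (population 100, 800 generations,
    2-point crossover at 0.80, mutation rate 0.04, roulette selection)."""

    pop_size: int = 100
    generations: int = 800
    crossover_prob: float = 0.80
    mutation_rate: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2 or self.generations < 1:
            raise ParameterError("need pop_size >= 2 and generations >= 1")
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_rate <= 1):
            raise ParameterError("probabilities must lie in [0, 1]")


@dataclass
class VariableBounds:
    """Search space: valid categorical codes and continuous ranges."""

    cultivar_codes: tuple[float, ...] = (1, 2)
    stress_codes: tuple[float, ...] = (0, 1, 2, 3)
    gaba_mM: tuple[float, float] = (0.0, 40.0)
    day: tuple[float, float] = (0.0, 45.0)


@dataclass
class NSGAResult:
    pareto: pd.DataFrame
    recommendation: dict
    history: pd.DataFrame
    population: np.ndarray
    objectives: np.ndarray
    fronts: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# NSGA-II primitives
# ---------------------------------------------------------------------------

def fast_non_dominated_sort(objectives: np.ndarray) -> list[np.ndarray]:
    """Partition points into non-dominated fronts (maximization sense).

    Returns index arrays; within a front no point dominates another, and
    every point of front k>1 is dominated by some point of front k-1.
    """
    F = np.asarray(objectives, dtype=float)
    if F.ndim != 2 or F.shape[0] < 1:
        raise ParameterError("need a non-empty 2-D objective array")
    if not np.isfinite(F).all():
        raise OptimizationError("non-finite objective values")
    n = F.shape[0]
    ge = (F[:, None, :] >= F[None, :, :]).all(axis=2)
    gt = (F[:, None, :] > F[None, :, :]).any(axis=2)
    dominates = ge & gt  # dominates[i, j]: i dominates j
    n_dominators = dominates.sum(axis=0)
    fronts = []
    remaining = np.ones(n, dtype=bool)
    while remaining.any():
        current = np.flatnonzero(remaining & (n_dominators == 0))
        if current.size == 0:  # pragma: no cover - defensive
            raise OptimizationError("dominance cycle; objectives not finite?")
        fronts.append(current)
        remaining[current] = False
        n_dominators = n_dominators - dominates[current].sum(axis=0)
    return fronts


def crowding_distance(front_objectives: np.ndarray) -> np.ndarray:
    """Crowding distance per front member: boundary members per
    objective get infinity, interior members the sum of normalized
    neighbour gaps.  Invariant to input permutation."""
    F = np.atleast_2d(np.asarray(front_objectives, dtype=float))
    n, m = F.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        vals = F[order, j]
        rng = vals[-1] - vals[0]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if rng > 0:
            gaps = (vals[2:] - vals[:-2]) / rng
            interior = order[1:-1]
            finite = np.isfinite(dist[interior])
            dist[interior[finite]] += gaps[finite]
    return dist


def roulette_selection(scores: np.ndarray, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Indices sampled with probability proportional to the scores."""
    scores = np.asarray(scores, dtype=float)
    if np.any(scores < 0):
        raise SelectionError("selection scores must be non-negative")
    total = scores.sum()
    if total <= 0:
        raise SelectionError("all selection scores are zero")
    cum = np.cumsum(scores) / total
    return np.searchsorted(cum, rng.random(n_draws), side="right").clip(0, len(scores) - 1)


def two_point_crossover(
    parent1: np.ndarray,
    parent2: np.ndarray,
    probability: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """With the given probability, exchange the gene segment between two
    cut points of the 4-gene vectors; otherwise return copies."""
    c1, c2 = parent1.copy(), parent2.copy()
    if rng.random() < probability:
        cuts = np.sort(rng.choice(np.arange(1, N_GENES), size=2, replace=False))
        lo, hi = int(cuts[0]), int(cuts[1])
        c1[lo:hi], c2[lo:hi] = parent2[lo:hi].copy(), parent1[lo:hi].copy()
    return c1, c2


def mutate(
    chromosome: np.ndarray,
    rate: float,
    bounds: VariableBounds,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reset each gene independently with the given rate: categoricals
    to a random valid code, reals to a uniform draw within bounds."""
    out = chromosome.copy()
    hit = rng.random(N_GENES) < rate
    if hit[0]:
        out[0] = rng.choice(bounds.cultivar_codes)
    if hit[1]:
        out[1] = rng.choice(bounds.stress_codes)
    if hit[2]:
        out[2] = rng.uniform(*bounds.gaba_mM)
    if hit[3]:
        out[3] = rng.uniform(*bounds.day)
    return out


def composite_fitness(objectives: np.ndarray, ideal: np.ndarray) -> np.ndarray:
    """Euclidean distance of each objective vector to the ideal point."""
    obj = np.atleast_2d(np.asarray(objectives, dtype=float))
    diff = obj - np.asarray(ideal, dtype=float)
    out = np.sqrt((diff**2).sum(axis=1))
    return out if np.asarray(objectives).ndim == 2 else float(out[0])


# ---------------------------------------------------------------------------
# the main loop
# ---------------------------------------------------------------------------

def _clip_population(pop: np.ndarray, bounds: VariableBounds) -> np.ndarray:
    pop = pop.copy()
    cult = np.asarray(bounds.cultivar_codes, float)
    stre = np.asarray(bounds.stress_codes, float)
    pop[:, 0] = cult[np.abs(pop[:, [0]] - cult[None, :]).argmin(axis=1)]
    pop[:, 1] = stre[np.abs(pop[:, [1]] - stre[None, :]).argmin(axis=1)]
    pop[:, 2] = np.clip(pop[:, 2], *bounds.gaba_mM)
    pop[:, 3] = np.clip(pop[:, 3], *bounds.day)
    return pop


def _survival(objectives: np.ndarray, n_keep: int, best_f_idx: int) -> np.ndarray:
    """Elitist environmental selection: fronts, then crowding.  The
    individual with the lowest composite fitness is always retained."""
    fronts = fast_non_dominated_sort(objectives)
    chosen: list[int] = []
    for front in fronts:
        if len(chosen) + len(front) <= n_keep:
            chosen.extend(front.tolist())
        else:
            dist = crowding_distance(objectives[front])
            order = np.argsort(-dist, kind="stable")
            chosen.extend(front[order[: n_keep - len(chosen)]].tolist())
            break
    if best_f_idx not in chosen:
        chosen[-1] = best_f_idx
    return np.asarray(chosen, dtype=int)


def run_nsga2(
    surrogate,
    config: NSGAConfig | None = None,
    bounds: VariableBounds | None = None,
    ideal: np.ndarray | None = None,
) -> NSGAResult:
    """Evolve the 5-objective maximization problem and return the final
    Pareto front plus the single ideal-point-best recommendation.

    ``surrogate`` needs ``predict_encoded`` (raw-encoded inputs to
    original-scale traits); the ideal point defaults to the surrogate's
    training-data trait maxima.  Deterministic given ``config.seed``.
    """
    config = config or NSGAConfig()
    bounds = bounds or VariableBounds()
    if ideal is None:
        ideal = getattr(surrogate, "y_train_max", None)
        if ideal is None:
            raise ParameterError("no ideal point given and none stored on the surrogate")
    ideal = np.asarray(ideal, dtype=float)
    rng = np.random.default_rng(config.seed)

    n = config.pop_size
    pop = np.column_stack(
        [
            rng.choice(bounds.cultivar_codes, size=n),
            rng.choice(bounds.stress_codes, size=n),
            rng.uniform(*bounds.gaba_mM, size=n),
            rng.uniform(*bounds.day, size=n),
        ]
    ).astype(float)
    obj = np.asarray(surrogate.predict_encoded(pop), dtype=float)
    if not np.isfinite(obj).all():
        raise OptimizationError("surrogate returned non-finite objectives at generation 0")
    fit = composite_fitness(obj, ideal)

    history = []
    for gen in range(config.generations):
        history.append(
            {"generation": gen, "best_F": float(fit.min()), "mean_F": float(fit.mean())}
        )
        parents_idx = roulette_selection(1.0 / (1.0 + fit), n, rng)
        offspring = []
        for i in range(0, n - 1, 2):
            a, b = two_point_crossover(
                pop[parents_idx[i]], pop[parents_idx[i + 1]], config.crossover_prob, rng
            )
            offspring.append(mutate(a, config.mutation_rate, bounds, rng))
            offspring.append(mutate(b, config.mutation_rate, bounds, rng))
        if len(offspring) < n:  # odd population size
            offspring.append(
                mutate(pop[parents_idx[-1]].copy(), config.mutation_rate, bounds, rng)
            )
        off = _clip_population(np.asarray(offspring[:n]), bounds)
        off_obj = np.asarray(surrogate.predict_encoded(off), dtype=float)
        if not np.isfinite(off_obj).all():
            raise OptimizationError(f"non-finite objectives at generation {gen + 1}")

        comb_pop = np.vstack([pop, off])
        comb_obj = np.vstack([obj, off_obj])
        comb_fit = composite_fitness(comb_obj, ideal)
        keep = _survival(comb_obj, n, int(np.argmin(comb_fit)))
        pop, obj, fit = comb_pop[keep], comb_obj[keep], comb_fit[keep]

    history.append(
        {
            "generation": config.generations,
            "best_F": float(fit.min()),
            "mean_F": float(fit.mean()),
        }
    )

    fronts = fast_non_dominated_sort(obj)
    front1 = fronts[0]
    pareto = _decode_frame(surrogate, pop[front1], obj[front1], fit[front1])
    best_local = int(np.argmin(fit[front1]))
    recommendation = pareto.iloc[best_local].to_dict()
    return NSGAResult(
        pareto=pareto,
        recommendation=recommendation,
        history=pd.DataFrame(history),
        population=pop,
        objectives=obj,
        fronts=[f for f in fronts],
    )


def _decode_frame(surrogate, pop: np.ndarray, obj: np.ndarray, fit: np.ndarray) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "cultivar_code": pop[:, 0],
            "stress_code": pop[:, 1],
            "gaba_mM": pop[:, 2],
            "day": pop[:, 3],
        }
    )
    encoding = getattr(surrogate, "encoding", None)
    if encoding is not None and not encoding.one_hot:
        inv_c = {v: k for k, v in encoding.cultivar_codes.items()}
        inv_s = {v: k for k, v in encoding.stress_codes.items()}
        frame.insert(0, "cultivar", [inv_c.get(c, c) for c in pop[:, 0]])
        frame.insert(1, "stress", [inv_s.get(s, s) for s in pop[:, 1]])
    trait_names = getattr(surrogate, "trait_names", TRAITS)
    for j, t in enumerate(trait_names):
        frame[f"pred_{t}"] = obj[:, j]
    frame["F"] = fit
    return frame.sort_values("F", kind="stable").reset_index(drop=True)
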