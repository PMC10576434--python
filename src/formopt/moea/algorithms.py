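"""The five classic multi-objective genetic algorithms.

All five share the real-coded representation, SBX crossover and
polynomial mutation from :mod:`formopt.moea.core`, and differ only in
selection and replacement:

* VEGA   — objective-wise subpopulations with proportional selection;
* MOGA   — Fonseca–Fleming ranking, objective-space fitness sharing,
           parent/offspring merge;
* NPGA   — Pareto-domination tournaments against a random comparison
           set, ties broken by decision-space niche counts;
* NSGA   — front peeling with shared virtual fitness, proportional
           selection, non-elitist replacement;
* NSGA-II — elitist (mu+lambda) loop with fast non-dominated sorting and
           crowding-distance truncation.

Each run keeps an archive of every non-dominated point evaluated, so a
"final front" is well defined even for the non-elitist methods, and
records a per-generation fitness trace (max and mean of each objective
over the current population).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .core import (
    AlgorithmOptions,
    GAParams,
    Individual,
    ParetoArchive,
    crowding_distance,
    fast_nondominated_sort,
    niche_counts,
    polynomial_mutation,
    ranks_from_fronts,
    sbx_crossover,
)

ObjectiveFn = Callable[[np.ndarray], np.ndarray]
Bounds = tuple[np.ndarray, np.ndarray]


@dataclass
class FitnessTrace:
    """Per-generation objective summaries of the evolving population.

    Row 0 is the initial random population (generation 0); rows 1..G are
    the evolved generations.
    """

    generation: np.ndarray
    max_y1: np.ndarray
    max_y2: np.ndarray
    mean_y1: np.ndarray
    mean_y2: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generation,
                "max_y1": self.max_y1,
                "max_y2": self.max_y2,
                "mean_y1": self.mean_y1,
                "mean_y2": self.mean_y2,
            }
        )

    def max_matrix(self, include_initial: bool = False) -> np.ndarray:
        """(G, 2) per-generation objective maxima (generation >= 1)."""
        start = 0 if include_initial else 1
        return np.column_stack([self.max_y1, self.max_y2])[start:]

    def __len__(self) -> int:
        return len(self.generation)


@dataclass
class RunResult:
    """Outcome of one seeded run of one algorithm."""

    algorithm: str
    seed: int | None
    final_front: list[Individual]
    trace: FitnessTrace
    evaluations: int

    @property
    def front_x(self) -> np.ndarray:
        return np.array([ind.x for ind in self.final_front])

    @property
    def front_objectives(self) -> np.ndarray:
        return np.array([ind.objectives for ind in self.final_front])

    def to_frame(self) -> pd.DataFrame:
        """One row per front member in the published table layout."""
        X = self.front_x
        F = self.front_objectives
        return pd.DataFrame(
            {
                "x1": X[:, 0],
                "x2": X[:, 1],
                "x3_pct": 100.0 * X[:, 2],
                "y1": F[:, 0],
                "y2": F[:, 1],
                "surfactant_pct": X[:, 0] * (95.0 - 100.0 * X[:, 2]),
            }
        )


class _Tracer:
    def __init__(self) -> None:
        self.rows: list[tuple] = []

    def record(self, gen: int, F: np.ndarray) -> None:
        self.rows.append((gen, F[:, 0].max(), F[:, 1].max(), F[:, 0].mean(), F[:, 1].mean()))

    def build(self) -> FitnessTrace:
        cols = list(zip(*self.rows))
        return FitnessTrace(
            generation=np.array(cols[0], int),
            max_y1=np.array(cols[1]),
            max_y2=np.array(cols[2]),
            mean_y1=np.array(cols[3]),
            mean_y2=np.array(cols[4]),
        )


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _init_population(bounds: Bounds, n: int, rng: np.random.Generator) -> np.ndarray:
    lower, upper = bounds
    return rng.uniform(lower, upper, size=(n, len(lower)))


def _positive_fitness(values: np.ndarray) -> np.ndarray:
    """Min-shift objective values for proportional selection.

    Plumbing: roulette wheels need positive weights, so values are
    shifted so the generation minimum keeps a 10%-of-range floor (uniform
    weights when the generation is flat).
    """
    v = np.asarray(values, float)
    ptp = v.max() - v.min()
    if ptp == 0:
        return np.ones_like(v)
    return (v - v.min()) + 0.1 * ptp


def _roulette(fitness: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    p = fitness / fitness.sum()
    return rng.choice(len(fitness), size=n, replace=True, p=p)


def _variation(
    parents: np.ndarray,
    bounds: Bounds,
    params: GAParams,
    options: AlgorithmOptions,
    rng: np.random.Generator,
) -> np.ndarray:
    """SBX on consecutive parent pairs, then per-gene polynomial mutation."""
    lower, upper = bounds
    n = len(parents)
    children = parents.copy()
    for i in range(0, n - 1, 2):
        if rng.random() < params.p_crossover:
            c1, c2 = sbx_crossover(
                parents[i],
                parents[i + 1],
                lower,
                upper,
                options.crossover_eta,
                rng,
                options.bound_repair,
            )
            children[i], children[i + 1] = c1, c2
    for i in range(n):
        children[i] = polynomial_mutation(
            children[i],
            lower,
            upper,
            options.mutation_eta,
            params.p_mutation,
            rng,
            options.bound_repair,
        )
    return children


def _normalize(X: np.ndarray, bounds: Bounds) -> np.ndarray:
    lower, upper = bounds
    return (X - lower) / (upper - lower)


def _front_individuals(archive: ParetoArchive) -> list[Individual]:
    order = np.lexsort((-archive.F[:, 1], -archive.F[:, 0]))
    return [
        Individual(x=archive.X[i].copy(), objectives=archive.F[i].copy(), rank=1)
        for i in order
    ]


def _dominated_by_any(F_set: np.ndarray, f: np.ndarray) -> bool:
    ge = np.all(F_set >= f, axis=1)
    gt = np.any(F_set > f, axis=1)
    return bool(np.any(ge & gt))


def run_vega(
    objectives: ObjectiveFn,
    bounds: Bounds,
    params: GAParams | None = None,
    options: AlgorithmOptions | None = None,
    rng=None,
) -> RunResult:
    """Vector Evaluated GA: k objective-wise subpopulations per generation.

    The population is randomly split into k equal subpopulations, each
    performing proportional selection on its own (min-shifted) objective;
    the selected parents are merged and recombined.
    """
    params = params or GAParams()
    options = options or AlgorithmOptions()
    rng = _as_rng(rng)
    N, k = params.pop_size, params.k
    if N % k != 0:
        raise ValueError("pop_size must be divisible by k")
    X = _init_population(bounds, N, rng)
    F = objectives(X)
    n_obj = F.shape[1]
    archive = ParetoArchive()
    archive.add(X, F)
    tracer = _Tracer()
    tracer.record(0, F)
    evals = N
    for gen in range(1, params.max_generations + 1):
        perm = rng.permutation(N)
        pool = []
        for j in range(k):
            sub = perm[j * (N // k) : (j + 1) * (N // k)]
            fit = _positive_fitness(F[sub, j % n_obj])
            pool.append(sub[_roulette(fit, N // k, rng)])
        mating = np.concatenate(pool)[rng.permutation(N)]
        X = _variation(X[mating], bounds, params, options, rng)
        F = objectives(X)
        evals += N
        archive.add(X, F)
        tracer.record(gen, F)
    return RunResult("VEGA", _seed_of(rng), _front_individuals(archive), tracer.build(), evals)


def _moga_fitness(
    F: np.ndarray, options: AlgorithmOptions
) -> tuple[np.ndarray, np.ndarray]:
    """Fonseca–Fleming rank (1 + dominator count) and shared fitness.

    Raw fitness interpolates linearly from len(F) (best) to 1 (worst) by
    rank-sorted position, averaged within equal ranks, then divided by an
    objective-space niche count (ranges normalized per generation).
    """
    n = len(F)
    ge = np.all(F[:, None, :] >= F[None, :, :], axis=2)
    gt = np.any(F[:, None, :] > F[None, :, :], axis=2)
    ranks = 1 + (ge & gt).sum(axis=0)
    order = np.argsort(ranks, kind="stable")
    raw = np.empty(n)
    raw[order] = np.linspace(n, 1, n)
    for r in np.unique(ranks):
        sel = ranks == r
        raw[sel] = raw[sel].mean()
    span = F.max(axis=0) - F.min(axis=0)
    span[span == 0] = 1.0
    shared = raw / niche_counts((F - F.min(axis=0)) / span, options.sigma_share)
    return ranks, shared


def run_moga(
    objectives: ObjectiveFn,
    bounds: Bounds,
    params: GAParams | None = None,
    options: AlgorithmOptions | None = None,
    rng=None,
) -> RunResult:
    """Multiple Objective GA: Pareto ranking with objective-space sharing.

    Each generation the parents are merged with their offspring and the
    next population is the best half of the merged pool under shared
    rank-based fitness.
    """
    params = params or GAParams()
    options = options or AlgorithmOptions()
    rng = _as_rng(rng)
    N = params.pop_size
    X = _init_population(bounds, N, rng)
    F = objectives(X)
    archive = ParetoArchive()
    archive.add(X, F)
    tracer = _Tracer()
    tracer.record(0, F)
    evals = N
    for gen in range(1, params.max_generations + 1):
        _, shared = _moga_fitness(F, options)
        parents = _roulette(shared, N, rng)
        Q = _variation(X[parents], bounds, params, options, rng)
        FQ = objectives(Q)
        evals += N
        archive.add(Q, FQ)
        RX = np.vstack([X, Q])
        RF = np.vstack([F, FQ])
        _, shared_r = _moga_fitness(RF, options)
        keep = np.argsort(-shared_r, kind="stable")[:N]
        X, F = RX[keep], RF[keep]
        tracer.record(gen, F)
    return RunResult("MOGA", _seed_of(rng), _front_individuals(archive), tracer.build(), evals)


def npga_tournament(
    i: int,
    j: int,
    cs: np.ndarray,
    F: np.ndarray,
    niche: np.ndarray,
) -> int:
    """One NPGA binary tournament against an external comparison set.

    A candidate dominated by any comparison-set member is "inferior to
    the set"; if exactly one candidate is inferior the other wins, else
    the smaller niche count wins (first candidate on ties).
    """
    F_cs = F[cs]
    i_dom = _dominated_by_any(F_cs, F[i])
    j_dom = _dominated_by_any(F_cs, F[j])
    if i_dom and not j_dom:
        return j
    if j_dom and not i_dom:
        return i
    return i if niche[i] <= niche[j] else j


def run_npga(
    objectives: ObjectiveFn,
    bounds: Bounds,
    params: GAParams | None = None,
    options: AlgorithmOptions | None = None,
    rng=None,
) -> RunResult:
    """Niched Pareto GA: domination tournaments + niche-count tie-breaks."""
    params = params or GAParams()
    options = options or AlgorithmOptions()
    rng = _as_rng(rng)
    N = params.pop_size
    if options.comparison_set_size >= N:
        raise ValueError("comparison_set_size must be smaller than pop_size")
    X = _init_population(bounds, N, rng)
    F = objectives(X)
    archive = ParetoArchive()
    archive.add(X, F)
    tracer = _Tracer()
    tracer.record(0, F)
    evals = N
    for gen in range(1, params.max_generations + 1):
        niche = niche_counts(_normalize(X, bounds), options.sigma_share)
        winners = np.empty(N, int)
        for t in range(N):
            i, j = rng.integers(0, N, size=2)
            cs = rng.choice(N, size=options.comparison_set_size, replace=False)
            winners[t] = npga_tournament(i, j, cs, F, niche)
        X = _variation(X[winners], bounds, params, options, rng)
        F = objectives(X)
        evals += N
        archive.add(X, F)
        tracer.record(gen, F)
    return RunResult("NPGA", _seed_of(rng), _front_individuals(archive), tracer.build(), evals)


def nsga_virtual_fitness(
    X: np.ndarray, F: np.ndarray, bounds: Bounds, options: AlgorithmOptions
) -> np.ndarray:
    """Front-wise virtual fitness, degraded by decision-space sharing.

    Front 1 starts at the population size; within a front the dummy value
    is divided by the triangular niche count (so equal-rank individuals
    have equal fitness before sharing), and the next front starts below
    90% of the previous front's smallest shared value, capped by the
    count of individuals not yet assigned.
    """
    n = len(F)
    fronts = fast_nondominated_sort(F)
    Xn = _normalize(X, bounds)
    vf = np.empty(n)
    base = float(n)
    assigned = 0
    for front in fronts:
        base = min(base, float(n - assigned))
        shared = base / niche_counts(Xn[front], options.sigma_share)
        vf[front] = shared
        base = 0.9 * shared.min()
        assigned += len(front)
    return vf


def run_nsga(
    objectives: ObjectiveFn,
    bounds: Bounds,
    params: GAParams | None = None,
    options: AlgorithmOptions | None = None,
    rng=None,
) -> RunResult:
    """Non-dominated Sorting GA (non-elitist, shared virtual fitness)."""
    params = params or GAParams()
    options = options or AlgorithmOptions()
    rng = _as_rng(rng)
    N = params.pop_size
    X = _init_population(bounds, N, rng)
    F = objectives(X)
    archive = ParetoArchive()
    archive.add(X, F)
    tracer = _Tracer()
    tracer.record(0, F)
    evals = N
    for gen in range(1, params.max_generations + 1):
        vf = nsga_virtual_fitness(X, F, bounds, options)
        parents = _roulette(vf, N, rng)
        X = _variation(X[parents], bounds, params, options, rng)
        F = objectives(X)
        evals += N
        archive.add(X, F)
        tracer.record(gen, F)
    return RunResult("NSGA", _seed_of(rng), _front_individuals(archive), tracer.build(), evals)


def _rank_and_crowding(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fronts = fast_nondominated_sort(F)
    ranks = ranks_from_fronts(fronts, len(F))
    crowd = np.empty(len(F))
    for front in fronts:
        crowd[front] = crowding_distance(F[front])
    return ranks, crowd


def run_nsga2(
    objectives: ObjectiveFn,
    bounds: Bounds,
    params: GAParams | None = None,
    options: AlgorithmOptions | None = None,
    rng=None,
) -> RunResult:
    """NSGA-II: elitist (mu+lambda) with crowding-distance truncation."""
    params = params or GAParams()
    options = options or AlgorithmOptions()
    rng = _as_rng(rng)
    N = params.pop_size
    X = _init_population(bounds, N, rng)
    F = objectives(X)
    archive = ParetoArchive()
    archive.add(X, F)
    tracer = _Tracer()
    tracer.record(0, F)
    evals = N
    for gen in range(1, params.max_generations + 1):
        ranks, crowd = _rank_and_crowding(F)
        # binary tournaments on (rank asc, crowding desc, index asc)
        a = rng.integers(0, N, size=N)
        b = rng.integers(0, N, size=N)
        a_wins = (ranks[a] < ranks[b]) | (
            (ranks[a] == ranks[b]) & (crowd[a] >= crowd[b])
        )
        parents = np.where(a_wins, a, b)
        Q = _variation(X[parents], bounds, params, options, rng)
        FQ = objectives(Q)
        evals += N
        archive.add(Q, FQ)
        RX = np.vstack([X, Q])
        RF = np.vstack([F, FQ])
        fronts = fast_nondominated_sort(RF)
        chosen: list[int] = []
        for front in fronts:
            if len(chosen) + len(front) <= N:
                chosen.extend(front.tolist())
            else:
                cd = crowding_distance(RF[front])
                order = np.argsort(-cd, kind="stable")
                chosen.extend(front[order][: N - len(chosen)].tolist())
                break
        X, F = RX[chosen], RF[chosen]
        tracer.record(gen, F)
    return RunResult("NSGA-II", _seed_of(rng), _front_individuals(archive), tracer.build(), evals)


def _seed_of(rng: np.random.Generator) -> int | None:
    # best-effort seed recovery for logging; None when not a plain integer seed
    try:
        state = rng.bit_generator.seed_seq  # type: ignore[union-attr]
        entropy = getattr(state, "entropy", None)
        return int(entropy) if isinstance(entropy, int) else None
    except AttributeError:
        return None


ALGORITHMS: dict[str, Callable[..., RunResult]] = {
    "vega": run_vega,
    "moga": run_moga,
    "npga": run_npga,
    "nsga": run_nsga,
    "nsga2": run_nsga2,
}
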