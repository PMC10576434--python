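"""Shared evolutionary machinery: dominance, sorting, diversity, variation.

Everything here is in *maximization* sense and pure given an explicit
``numpy.random.Generator``; ties break by stable population index so a
seeded run is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlgorithmOptions",
    "GAParams",
    "Individual",
    "ParetoArchive",
    "crowding_distance",
    "dominates",
    "fast_nondominated_sort",
    "niche_counts",
    "non_dominated_filter",
    "non_dominated_mask",
    "pareto_front_2d_mask",
    "polynomial_mutation",
    "sbx_crossover",
]


@dataclass
class GAParams:
    """Run-length and variation-rate parameters shared by all algorithms."""

    pop_size: int = 30
    p_crossover: float = 0.8
    p_mutation: float = 0.05  # per gene
    max_generations: int = 100
    n_searches: int = 30
    k: int = 2  # number of sub-objectives (VEGA subpopulations)

    def __post_init__(self) -> None:
        for p in (self.p_crossover, self.p_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.pop_size % self.k != 0:
            raise ValueError("pop_size must be divisible by the number of sub-objectives")


@dataclass
class AlgorithmOptions:
    """Operator-level knobs that the study itself leaves unspecified."""

    sigma_share: float = 0.1  # niche radius in the normalized decision space
    comparison_set_size: int = 10  # NPGA external comparison set
    crossover_eta: float = 15.0  # SBX distribution index
    mutation_eta: float = 20.0  # polynomial-mutation distribution index
    bound_repair: str = "clip"  # "clip" | "reflect"

    def __post_init__(self) -> None:
        if self.sigma_share <= 0:
            raise ValueError("sigma_share must be positive")
        if self.bound_repair not in ("clip", "reflect"):
            raise ValueError("bound_repair must be 'clip' or 'reflect'")


@dataclass
class Individual:
    """A real-coded candidate with its evaluated objective vector."""

    x: np.ndarray
    objectives: np.ndarray
    rank: int | None = None
    crowding: float | None = None
    niche_count: float | None = None
    virtual_fitness: float | None = None


def dominates(a, b) -> bool:
    """True iff ``a`` Pareto-dominates ``b`` under maximization.

    a >= b in every component and a > b in at least one.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"objective dimension mismatch: {a.shape} vs {b.shape}")
    return bool(np.all(a >= b) and np.any(a > b))


def _domination_matrix(F: np.ndarray) -> np.ndarray:
    """D[i, j] == True iff individual i dominates individual j."""
    ge = np.all(F[:, None, :] >= F[None, :, :], axis=2)
    gt = np.any(F[:, None, :] > F[None, :, :], axis=2)
    return ge & gt


def non_dominated_mask(F: np.ndarray) -> np.ndarray:
    """Boolean mask of the maximal (non-dominated) points; O(n²) pairwise.

    This brute-force filter is the package's dominance oracle.
    """
    F = np.atleast_2d(np.asarray(F, float))
    n = len(F)
    if n == 0:
        return np.zeros(0, bool)
    if n > 20000:
        raise ValueError("pairwise filter beyond 20000 points; use pareto_front_2d_mask")
    return ~_domination_matrix(F).any(axis=0)


def non_dominated_filter(points) -> np.ndarray:
    """Indices of the non-dominated points, in input order."""
    mask = non_dominated_mask(np.asarray(points, float))
    return np.flatnonzero(mask)


def pareto_front_2d_mask(F: np.ndarray) -> np.ndarray:
    """Non-dominated mask for two maximized objectives in O(n log n).

    Sweep over groups of equal f1 in decreasing order.  A point is
    non-dominated iff its f2 is the maximum within its f1-group (group
    ties are mutual duplicates, all kept under strict dominance) and
    strictly exceeds every f2 seen at strictly larger f1.
    """
    F = np.atleast_2d(np.asarray(F, float))
    if F.shape[1] != 2:
        raise ValueError("pareto_front_2d_mask requires exactly 2 objectives")
    n = len(F)
    mask = np.zeros(n, bool)
    order = np.lexsort((-F[:, 1], -F[:, 0]))
    best2 = -np.inf  # max f2 among points with strictly larger f1
    i = 0
    while i < n:
        f1 = F[order[i], 0]
        j = i
        while j < n and F[order[j], 0] == f1:
            j += 1
        group = order[i:j]
        group_max = F[group[0], 1]  # lexsort put max f2 first within the group
        if group_max > best2:
            mask[group[F[group, 1] == group_max]] = True
        best2 = max(best2, group_max)
        i = j
    return mask


class ParetoArchive:
    """All-evaluations archive reduced to its non-dominated subset.

    Keeping the archive makes "final front" well defined even for the
    non-elitist algorithms.
    """

    def __init__(self) -> None:
        self.X = np.empty((0, 0))
        self.F = np.empty((0, 0))

    def add(self, X: np.ndarray, F: np.ndarray) -> None:
        X = np.atleast_2d(X)
        F = np.atleast_2d(F)
        if self.X.size == 0:
            allX, allF = X, F
        else:
            allX = np.vstack([self.X, X])
            allF = np.vstack([self.F, F])
        mask = (
            pareto_front_2d_mask(allF) if allF.shape[1] == 2 else non_dominated_mask(allF)
        )
        self.X = allX[mask]
        self.F = allF[mask]

    def __len__(self) -> int:
        return len(self.X)


def fast_nondominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Deb's fast non-dominated sort; returns index arrays per front.

    Front 1 is the maximal set; front f is the maximal set once fronts
    < f are removed.  Concatenated fronts partition the population.
    """
    F = np.atleast_2d(np.asarray(F, float))
    n = len(F)
    D = _domination_matrix(F)
    n_dominators = D.sum(axis=0).astype(int)
    fronts: list[np.ndarray] = []
    current = np.flatnonzero(n_dominators == 0)
    remaining = n_dominators.copy()
    assigned = np.zeros(n, bool)
    while current.size:
        fronts.append(current)
        assigned[current] = True
        # remove this front: decrement dominator counts of its dominatees
        dec = D[current].sum(axis=0)
        remaining = remaining - dec
        current = np.flatnonzero((remaining == 0) & ~assigned)
    return fronts


def ranks_from_fronts(fronts: list[np.ndarray], n: int) -> np.ndarray:
    ranks = np.empty(n, int)
    for r, idx in enumerate(fronts, start=1):
        ranks[idx] = r
    return ranks


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """Crowding distances within one (internally non-dominated) front.

    Per objective the front is sorted; boundary individuals receive +inf
    and interior ones the normalized gap between their neighbours.  An
    objective with zero range contributes nothing.
    """
    F = np.atleast_2d(np.asarray(F, float))
    n, m = F.shape
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        fj = F[order, j]
        rng = fj[-1] - fj[0]
        d[order[0]] = np.inf
        d[order[-1]] = np.inf
        if rng > 0:
            d[order[1:-1]] += (fj[2:] - fj[:-2]) / rng
    return d


def niche_counts(P: np.ndarray, sigma_share: float) -> np.ndarray:
    """Triangular-sharing niche counts over a normalized point cloud.

    sh(d) = 1 − d/σ for d < σ, else 0; the count is Σ_j sh(d_ij), which
    is 1 for an isolated individual (self-share) and 2 for each of two
    coincident ones.
    """
    if sigma_share <= 0:
        raise ValueError("sigma_share must be positive")
    P = np.atleast_2d(np.asarray(P, float))
    d = np.sqrt(((P[:, None, :] - P[None, :, :]) ** 2).sum(axis=2))
    sh = np.clip(1.0 - d / sigma_share, 0.0, None)
    return sh.sum(axis=1)


def _repair(child: np.ndarray, lower: np.ndarray, upper: np.ndarray, how: str) -> np.ndarray:
    if how == "reflect":
        span = upper - lower
        y = np.mod(child - lower, 2 * span)
        child = lower + np.where(y > span, 2 * span - y, y)
    return np.clip(child, lower, upper)


def sbx_crossover(
    p1: np.ndarray,
    p2: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    eta: float,
    rng: np.random.Generator,
    bound_repair: str = "clip",
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover (per-gene, 0.5 exchange probability).

    Large ``eta`` contracts the spread factor towards 1, so offspring
    approach their parents.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    u = rng.random(p1.shape)
    beta = np.where(
        u <= 0.5,
        (2.0 * u) ** (1.0 / (eta + 1.0)),
        (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)),
    )
    apply = rng.random(p1.shape) < 0.5
    beta = np.where(apply, beta, 1.0)
    c1 = 0.5 * ((1.0 + beta) * p1 + (1.0 - beta) * p2)
    c2 = 0.5 * ((1.0 - beta) * p1 + (1.0 + beta) * p2)
    return (
        _repair(c1, lower, upper, bound_repair),
        _repair(c2, lower, upper, bound_repair),
    )


def polynomial_mutation(
    x: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    eta: float,
    p_mutation: float,
    rng: np.random.Generator,
    bound_repair: str = "clip",
) -> np.ndarray:
    """Bounded polynomial mutation, applied per gene with ``p_mutation``."""
    x = np.asarray(x, float).copy()
    span = upper - lower
    genes = rng.random(x.shape) < p_mutation
    u = rng.random(x.shape)
    d1 = (x - lower) / span
    d2 = (upper - x) / span
    mexp = 1.0 / (eta + 1.0)
    low_side = (2.0 * u + (1.0 - 2.0 * u) * (1.0 - d1) ** (eta + 1.0)) ** mexp - 1.0
    high_side = 1.0 - (2.0 * (1.0 - u) + 2.0 * (u - 0.5) * (1.0 - d2) ** (eta + 1.0)) ** mexp
    delta = np.where(u < 0.5, low_side, high_side)
    x = np.where(genes, x + delta * span, x)
    return _repair(x, lower, upper, bound_repair)
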