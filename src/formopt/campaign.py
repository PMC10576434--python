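"""Multi-seed search campaigns, representative fronts and summaries.

The study design runs each algorithm as 30 independently seeded
searches.  The per-seed archive fronts are pooled, reduced to a global
non-dominated set, and thinned to a fixed number of representative
solutions by crowding-distance ranking (objective-space extremes are
always retained).  Summaries report medians, quartiles and Shapiro–Wilk
normality per variable, matching the study's descriptive convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import QuadraticModel
from .formulation import LOWER, UPPER, make_objective_function, surfactant_percent
from .moea.algorithms import ALGORITHMS, FitnessTrace, RunResult
from .moea.core import (
    AlgorithmOptions,
    GAParams,
    Individual,
    crowding_distance,
    non_dominated_mask,
    pareto_front_2d_mask,
)

#: hard cap on grid-enumeration size (memory guard)
MAX_GRID_POINTS = 10_000_000


@dataclass
class SummaryRow:
    """Median / quartile / normality summary of one variable."""

    variable: str
    median: float
    p25: float
    p75: float
    iqr: float
    shapiro_w: float | None
    shapiro_p: float | None


@dataclass
class SchemeChoice:
    """The "ideal" scheme(s) picked from a representative solution set."""

    chosen: list[Individual]
    criterion_trace: pd.DataFrame


@dataclass
class CampaignResult:
    """Thirty seeded runs of one algorithm, pooled and summarized."""

    algorithm: str
    runs: list[RunResult]
    representative: list[Individual]
    convergence: list[int]
    params: GAParams

    @property
    def representative_frame(self) -> pd.DataFrame:
        X = np.array([ind.x for ind in self.representative])
        F = np.array([ind.objectives for ind in self.representative])
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


def thin_by_crowding(X: np.ndarray, F: np.ndarray, n: int) -> np.ndarray:
    """Indices of up to ``n`` representatives of a non-dominated set.

    One-shot crowding-distance ranking: extremes carry infinite distance
    and are always kept; ties keep the earlier (stable) index.  When the
    set has fewer than ``n`` members all are returned (no padding).
    """
    if len(F) <= n:
        return np.arange(len(F))
    cd = crowding_distance(F)
    order = np.argsort(-cd, kind="stable")
    return np.sort(order[:n])


def run_campaign(
    algorithm: str,
    objectives,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    params: GAParams | None = None,
    options: AlgorithmOptions | None = None,
    seeds=None,
) -> CampaignResult:
    """Run ``len(seeds)`` independent searches and pool their fronts.

    ``algorithm`` is one of vega/moga/npga/nsga/nsga2.  Seeds must be
    distinct; each seeds one full GA run.  The pooled archive fronts are
    re-filtered for global non-dominance and thinned to
    ``params.n_searches`` representatives.
    """
    if algorithm not in ALGORITHMS:
        raise KeyError(f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}")
    params = params or GAParams()
    options = options or AlgorithmOptions()
    bounds = bounds if bounds is not None else (LOWER, UPPER)
    if seeds is None:
        seeds = list(range(params.n_searches))
    seeds = [int(s) for s in seeds]
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    runner = ALGORITHMS[algorithm]
    runs: list[RunResult] = []
    for seed in seeds:
        try:
            runs.append(runner(objectives, bounds, params, options, rng=seed))
        except Exception as err:  # noqa: BLE001 - annotate the failing seed
            raise RuntimeError(f"{algorithm} run with seed {seed} failed: {err}") from err
    pooled_x = np.vstack([r.front_x for r in runs])
    pooled_f = np.vstack([r.front_objectives for r in runs])
    mask = (
        pareto_front_2d_mask(pooled_f)
        if pooled_f.shape[1] == 2
        else non_dominated_mask(pooled_f)
    )
    pooled_x, pooled_f = pooled_x[mask], pooled_f[mask]
    keep = thin_by_crowding(pooled_x, pooled_f, params.n_searches)
    representative = [
        Individual(x=pooled_x[i].copy(), objectives=pooled_f[i].copy(), rank=1)
        for i in keep
    ]
    convergence = [convergence_generation(r.trace) for r in runs]
    return CampaignResult(algorithm, runs, representative, convergence, params)


def convergence_generation(trace: FitnessTrace | np.ndarray, rel_tol: float = 0.01) -> int:
    """First generation after which both max-fitness traces stay settled.

    Smallest generation g (1-based) such that every later entry of each
    objective's running maximum lies within ``rel_tol`` (relative) of the
    final value.  The initial random population (generation 0) is not
    counted as an evolution generation.
    """
    if isinstance(trace, FitnessTrace):
        M = trace.max_matrix(include_initial=False)
    else:
        M = np.atleast_2d(np.asarray(trace, float))
        if M.shape[0] == 1:
            M = M.T
    if len(M) == 0:
        raise ValueError("empty trace")
    final = M[-1]
    tol = rel_tol * np.maximum(np.abs(final), 1e-12)
    ok = np.all(np.abs(M - final) <= tol, axis=1)
    g = len(M)
    while g > 1 and ok[g - 2]:
        g -= 1
    return g


def select_ideal(
    campaign: CampaignResult, tie_tol: float = 0.01, bound_tol: float = 0.005
) -> SchemeChoice:
    """Pick the "ideal" scheme(s) from the representative set.

    Deterministic rule: (1) keep the (already non-dominated)
    representatives; (2) among members whose water fraction sits at the
    upper bound (within ``bound_tol``), flag the max-permeation and the
    max-retention solutions; (3) among near-ties (within ``tie_tol`` in
    the flagged objective) prefer the lower surfactant percentage.
    """
    inds = campaign.representative
    if not inds:
        raise ValueError("empty representative set")
    X = np.array([i.x for i in inds])
    F = np.array([i.objectives for i in inds])
    x3_ub = UPPER[2]
    at_bound = X[:, 2] >= x3_ub - bound_tol
    pool = np.flatnonzero(at_bound) if at_bound.any() else np.arange(len(inds))
    surf = np.array([surfactant_percent(x) for x in X])
    chosen_idx: list[int] = []
    rows = []
    for obj in (0, 1):
        best = F[pool, obj].max()
        near = pool[F[pool, obj] >= best - tie_tol]
        pick = near[np.argmin(surf[near])]
        if pick not in chosen_idx:
            chosen_idx.append(int(pick))
        rows.append(
            {
                "flagged_objective": "y1" if obj == 0 else "y2",
                "best_value": best,
                "picked_index": int(pick),
                "picked_y1": F[pick, 0],
                "picked_y2": F[pick, 1],
                "picked_surfactant_pct": surf[pick],
            }
        )
    return SchemeChoice(
        chosen=[inds[i] for i in chosen_idx], criterion_trace=pd.DataFrame(rows)
    )


def summarize_campaign(campaign: CampaignResult) -> pd.DataFrame:
    """Median/P25/P75/IQR and Shapiro–Wilk normality per variable.

    Quartiles use linear interpolation between order statistics.  The
    water content is summarized in percent.  Degenerate (constant)
    variables get missing W and p.
    """
    if len(campaign.representative) < 3:
        raise ValueError("need at least 3 representative solutions to summarize")
    frame = campaign.representative_frame
    rows = []
    for var in ("x1", "x2", "x3_pct", "y1", "y2"):
        v = frame[var].to_numpy(float)
        p25, med, p75 = np.percentile(v, [25, 50, 75])  # linear interpolation
        if np.ptp(v) == 0:
            w = p = None
        else:
            w, p = sps.shapiro(v)
            w, p = float(w), float(p)
        rows.append(
            SummaryRow(
                variable=var, median=float(med), p25=float(p25), p75=float(p75),
                iqr=float(p75 - p25), shapiro_w=w, shapiro_p=p,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def grid_pareto_oracle(
    objectives,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    steps: tuple[int, int, int] = (41, 151, 41),
) -> tuple[np.ndarray, np.ndarray]:
    """Reference Pareto front by exhaustive grid enumeration.

    Evaluates the objectives on a rectangular grid (default 41×151×41)
    and keeps the non-dominated points.  Returns (front_x, front_f),
    sorted by decreasing first objective.
    """
    bounds = bounds if bounds is not None else (LOWER, UPPER)
    lower, upper = bounds
    if any(s < 2 for s in steps):
        raise ValueError("need at least 2 steps per axis")
    n_points = int(np.prod(steps))
    if n_points > MAX_GRID_POINTS:
        raise ValueError(f"grid of {n_points} points exceeds the {MAX_GRID_POINTS} guard")
    axes = [np.linspace(lower[d], upper[d], steps[d]) for d in range(len(steps))]
    G = np.array(np.meshgrid(*axes, indexing="ij")).reshape(len(steps), -1).T
    F = np.atleast_2d(objectives(G))
    mask = pareto_front_2d_mask(F) if F.shape[1] == 2 else non_dominated_mask(F)
    order = np.lexsort((-F[mask][:, 1], -F[mask][:, 0]))
    return G[mask][order], F[mask][order]


def hypervolume_2d(F: np.ndarray, ref: np.ndarray) -> float:
    """Dominated hypervolume of a 2-objective set w.r.t. ``ref`` (maximization)."""
    F = np.atleast_2d(np.asarray(F, float))
    ref = np.asarray(ref, float)
    mask = pareto_front_2d_mask(F)
    P = F[mask]
    P = P[np.all(P > ref, axis=1)]
    if len(P) == 0:
        return 0.0
    P = P[np.argsort(-P[:, 0], kind="stable")]
    hv = 0.0
    y_prev = ref[1]
    for y1, y2 in P:
        if y2 > y_prev:
            hv += (y1 - ref[0]) * (y2 - y_prev)
            y_prev = y2
    return float(hv)


def study_problem(
    models: tuple[QuadraticModel, QuadraticModel] | None = None,
):
    """The published optimization problem: objectives, models, bounds.

    By default the permeation-rate objective is the *published* Y1
    polynomial and the retention objective is the Y2 model refit to the
    design table — the pairing that reproduces the published search
    behaviour (see the methods note).
    """
    if models is None:
        from .fixtures import published_objective_models

        models = published_objective_models()
    m1, m2 = models
    return make_objective_function(m1, m2), (m1, m2), (LOWER, UPPER)
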