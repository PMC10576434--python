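"""Box-Behnken designs and full second-order response-surface models.

The experimental layer of the package: a 3-factor, 3-level Box-Behnken
design (12 edge-midpoint runs plus centre replicates) and the 10-term
quadratic polynomial

    y = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j

fitted by ordinary least squares to the run means.  The third factor
(water content) is expressed in percent in all tables and I/O, but
enters every model as a mass fraction (divided by 100); this is the
convention under which the published polynomials reproduce the
published predictions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

#: canonical term ordering of the 10-coefficient quadratic model
TERM_NAMES = ("b0", "b1", "b2", "b3", "b11", "b22", "b33", "b12", "b13", "b23")

#: response names carried by a design table (Y3 is carried, never modelled)
RESPONSES = ("Y1", "Y2", "Y3")

FACTOR_COLUMNS = ("x1", "x2", "x3_pct")


class UnsupportedDesignError(ValueError):
    """Raised when a design other than a 3-factor Box-Behnken is requested."""


class SingularFitError(ValueError):
    """Raised when the quadratic design matrix is rank deficient."""


@dataclass(frozen=True)
class FactorSpec:
    """One design factor with three ascending natural levels.

    The centre level need not be the arithmetic midpoint (the oil-ratio
    factor uses levels 0.25 / 1 / 4).
    """

    name: str
    levels: tuple[float, float, float]
    unit: str = ""

    def __post_init__(self) -> None:
        if len(self.levels) != 3:
            raise ValueError(f"factor {self.name!r}: exactly three levels required")
        lo, mid, hi = self.levels
        if not (lo < mid < hi):
            raise ValueError(f"factor {self.name!r}: levels must be strictly increasing")

    @property
    def low(self) -> float:
        return self.levels[0]

    @property
    def centre(self) -> float:
        return self.levels[1]

    @property
    def high(self) -> float:
        return self.levels[2]


def study_factors() -> tuple[FactorSpec, FactorSpec, FactorSpec]:
    """The three microemulsion preparation factors at their studied levels."""
    return (
        FactorSpec("x1", (0.6, 0.7, 0.8), unit="S/(O+S) mass fraction"),
        FactorSpec("x2", (0.25, 1.0, 4.0), unit="OL/(ALA+LA) mass ratio"),
        FactorSpec("x3", (65.0, 70.0, 75.0), unit="% water"),
    )


@dataclass
class DesignTable:
    """A Box-Behnken design with (optionally) replicate-summary responses.

    ``data`` holds one row per run with factor settings in natural units
    (columns ``x1``, ``x2``, ``x3_pct``) and, per response R present,
    columns ``R_mean`` and ``R_sd``.  ``n_rep`` is the replicate count
    behind each mean/SD pair.
    """

    data: pd.DataFrame
    n_rep: int = 6
    factors: tuple[FactorSpec, ...] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in FACTOR_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"design table missing factor columns {missing}")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_runs(self) -> int:
        return len(self.data)

    @property
    def responses(self) -> tuple[str, ...]:
        return tuple(r for r in RESPONSES if f"{r}_mean" in self.data.columns)

    def factor_settings(self, x3_as_fraction: bool = True) -> np.ndarray:
        """(n_runs, 3) factor settings; water content as fraction by default."""
        x = self.data.loc[:, list(FACTOR_COLUMNS)].to_numpy(float)
        if x3_as_fraction:
            x = x.copy()
            x[:, 2] /= 100.0
        return x

    def response_means(self, response: str) -> np.ndarray:
        return self.data[f"{response}_mean"].to_numpy(float)

    def response_sds(self, response: str) -> np.ndarray | None:
        col = f"{response}_sd"
        if col not in self.data.columns:
            return None
        return self.data[col].to_numpy(float)

    def level_counts(self, factors: tuple[FactorSpec, ...] | None = None) -> pd.DataFrame:
        """Occurrences of each factor's low/centre/high level across runs."""
        factors = factors or self.factors or study_factors()
        out = []
        for col, spec in zip(FACTOR_COLUMNS, factors):
            vals = self.data[col].to_numpy(float)
            out.append(
                {
                    "factor": spec.name,
                    "low": int(np.isclose(vals, spec.low).sum()),
                    "centre": int(np.isclose(vals, spec.centre).sum()),
                    "high": int(np.isclose(vals, spec.high).sum()),
                }
            )
        return pd.DataFrame(out)

    def validate(self, factors: tuple[FactorSpec, ...] | None = None) -> None:
        """Check the 3-factor BBD invariants; raise ValueError on violation.

        15 runs (12 edges + 3 centres), the 4/4/7 level-count pattern per
        factor, nonnegative SDs, and — when the particle-size response is
        present — all means below the 100 nm transdermal ceiling.
        """
        if self.n_runs != 15:
            raise ValueError(
                f"expected 15 runs (12 edge + 3 centre design points), got {self.n_runs}"
            )
        counts = self.level_counts(factors)
        for _, row in counts.iterrows():
            if (row["low"], row["high"], row["centre"]) != (4, 4, 7):
                raise ValueError(
                    f"factor {row['factor']}: level counts low/centre/high = "
                    f"{row['low']}/{row['centre']}/{row['high']}, expected 4/7/4"
                )
        for resp in self.responses:
            sds = self.response_sds(resp)
            if sds is not None and np.any(sds < 0):
                raise ValueError(f"{resp}: negative SD")
        if "Y3_mean" in self.data.columns:
            if np.any(self.data["Y3_mean"].to_numpy(float) >= 100):
                raise ValueError("Y3 (particle size) mean >= 100 nm")


def build_bbd(
    factors: tuple[FactorSpec, FactorSpec, FactorSpec] | list[FactorSpec],
    centre_reps: int = 3,
) -> DesignTable:
    """Construct the 3-factor Box-Behnken design at natural levels.

    Canonical run ordering: for each factor pair (1,2), (1,3), (2,3) the
    four (low/high) combinations in the order (−,−), (−,+), (+,−), (+,+)
    with the remaining factor at its centre, followed by ``centre_reps``
    all-centre runs.
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise UnsupportedDesignError(
            f"only 3-factor Box-Behnken designs are supported, got {len(factors)} factors"
        )
    if centre_reps < 1:
        raise ValueError("centre_reps must be >= 1")
    centre = [f.centre for f in factors]
    rows = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        for si, sj in ((0, 0), (0, 2), (2, 0), (2, 2)):
            run = list(centre)
            run[i] = factors[i].levels[si]
            run[j] = factors[j].levels[sj]
            rows.append(run)
    rows.extend([list(centre)] * centre_reps)
    data = pd.DataFrame(rows, columns=list(FACTOR_COLUMNS))
    data.insert(0, "run", np.arange(1, len(data) + 1))
    return DesignTable(data=data, factors=factors)


def quadratic_design_matrix(x: np.ndarray) -> np.ndarray:
    """Expand (n, 3) factor settings into the (n, 10) quadratic model matrix.

    Column order follows :data:`TERM_NAMES`.
    """
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[1] != 3:
        raise ValueError(f"expected 3 factors, got {x.shape[1]}")
    x1, x2, x3 = x.T
    return np.column_stack(
        [np.ones_like(x1), x1, x2, x3, x1 * x1, x2 * x2, x3 * x3, x1 * x2, x1 * x3, x2 * x3]
    )


@dataclass
class QuadraticModel:
    """A full second-order polynomial in the three formulation factors.

    ``coef`` holds the 10 coefficients in :data:`TERM_NAMES` order.  The
    model always takes the water content as a mass fraction (0.65–0.75);
    tables and reports use percent.
    """

    coef: np.ndarray
    response_name: str = ""
    x3_is_fraction: bool = True

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, float)
        if self.coef.shape != (10,):
            raise ValueError("a 3-factor quadratic model has exactly 10 coefficients")

    @classmethod
    def from_terms(cls, terms: dict[str, float], **kw) -> "QuadraticModel":
        return cls(coef=np.array([terms[t] for t in TERM_NAMES], float), **kw)

    def as_series(self) -> pd.Series:
        return pd.Series(self.coef, index=list(TERM_NAMES), name=self.response_name)

    def predict(self, x) -> np.ndarray | float:
        """Evaluate the polynomial at one point (3,) or many (n, 3).

        Pure evaluation: no bounds checking, no rounding.  ``x[...,2]``
        must be the water mass fraction.
        """
        x = np.asarray(x, float)
        single = x.ndim == 1
        y = quadratic_design_matrix(np.atleast_2d(x)) @ self.coef
        return float(y[0]) if single else y


def predict(model: QuadraticModel, x) -> np.ndarray | float:
    """Module-level alias for :meth:`QuadraticModel.predict`."""
    return model.predict(x)


@dataclass
class FitStats:
    """Goodness of fit of a quadratic model on a design table.

    ``r_squared`` is the mean-level convention (computed on the run
    means, the package default); ``r_squared_replicate`` reconstructs the
    replicate-level value from the per-run SDs when they are available.
    """

    r_squared: float
    sse: float
    sst: float
    n_points: int
    r_squared_replicate: float | None = None


def _check_full_rank(A: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # QR with column pivoting: the pivots beyond the numerical rank
        # identify which model terms are collinear with the rest.
        _, _, piv = scipy.linalg.qr(A, pivoting=True)
        bad = sorted(TERM_NAMES[k] for k in piv[rank:])
        raise SingularFitError(
            f"design matrix is rank deficient (rank {rank} < {A.shape[1]}); "
            f"collinear terms: {', '.join(bad)}"
        )


def fit_quadratic(
    design: DesignTable, response: str = "Y1"
) -> tuple[QuadraticModel, FitStats]:
    """Ordinary least-squares fit of the 10-term model to the run means.

    The water column is converted from percent to mass fraction before
    fitting.  Requires at least 10 distinct design points.
    """
    if f"{response}_mean" not in design.data.columns:
        raise KeyError(f"response {response!r} not present in design table")
    x = design.factor_settings(x3_as_fraction=True)
    if len(np.unique(x, axis=0)) < 10:
        raise ValueError("need >= 10 distinct design points to fit 10 coefficients")
    A = quadratic_design_matrix(x)
    _check_full_rank(A)
    y = design.response_means(response)
    res = sm.OLS(y, A).fit()
    model = QuadraticModel(coef=np.asarray(res.params), response_name=response)
    stats = FitStats(
        r_squared=float(res.rsquared),
        sse=float(res.ssr),
        sst=float(res.centered_tss),
        n_points=len(y),
    )
    return model, stats


def r_squared_replicate(
    design: DesignTable, model: QuadraticModel, response: str = "Y1"
) -> FitStats:
    """R² of ``model`` on ``design`` under both replicate conventions.

    Mean-level: 1 − SSE/SST on the run means.  Replicate-level: the sums
    of squares a fit on the full replicate data would produce, rebuilt
    from means and SDs under balance,

        SST_rep = n·SST_means + Σ (n−1) s²
        SSE_rep = n·SSE_means + Σ (n−1) s²

    (within-run scatter inflates both, so the replicate-level R² is never
    above the mean-level one).  If the SD column is absent the
    replicate-level entry is ``None``.
    """
    x = design.factor_settings(x3_as_fraction=model.x3_is_fraction)
    y = design.response_means(response)
    yhat = model.predict(x)
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    stats = FitStats(r_squared=1.0 - sse / sst, sse=sse, sst=sst, n_points=len(y))
    sds = design.response_sds(response)
    if sds is not None and not np.any(np.isnan(sds)):
        n = design.n_rep
        within = float(np.sum((n - 1) * sds**2))
        stats.r_squared_replicate = 1.0 - (n * sse + within) / (n * sst + within)
    return stats
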