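"""Decision variables, objectives and recipe arithmetic for the microemulsion.

A candidate formulation is the triple (x1, x2, x3):

* ``x1`` — surfactant share of the non-aqueous phase, S/(O+S), 0.6–0.8;
* ``x2`` — olive-oil to essential-fatty-acid mass ratio, OL/(ALA+LA), 0.25–4;
* ``x3`` — water mass fraction, 0.65–0.75 (printed as percent in tables).

The drug load is fixed at 5% lidocaine, so oil plus surfactant occupy
``95 − water%`` of the mass.  Fixed internal ratios (RH40:Span80 = 5:1,
mixed-oil:VES = 6:1, ALA:LA = 1:4) close the recipe exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np

from .design import QuadraticModel

#: box bounds of the decision space (x3 as mass fraction)
LOWER = np.array([0.6, 0.25, 0.65])
UPPER = np.array([0.8, 4.0, 0.75])

#: fixed lidocaine load, percent by mass
LIDOCAINE_PCT = 5.0


class OutOfBoundsWarning(UserWarning):
    """A formulation outside the studied factor box (model extrapolation)."""


@dataclass(frozen=True)
class FormulationVariables:
    """A point of the decision space; ``x3`` is the water mass fraction."""

    x1: float
    x2: float
    x3: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("formulation variables must be finite")
        if not self.in_bounds():
            warnings.warn(
                f"formulation {tuple(arr)} lies outside the studied box "
                f"[{LOWER.tolist()}, {UPPER.tolist()}]; model predictions are "
                "extrapolations",
                OutOfBoundsWarning,
                stacklevel=3,
            )

    @classmethod
    def from_percent(cls, x1: float, x2: float, x3_pct: float) -> "FormulationVariables":
        return cls(x1, x2, x3_pct / 100.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3], float)

    @property
    def x3_pct(self) -> float:
        return 100.0 * self.x3

    def in_bounds(self, tol: float = 1e-9) -> bool:
        arr = self.as_array()
        return bool(np.all(arr >= LOWER - tol) and np.all(arr <= UPPER + tol))


class ObjectiveVector(NamedTuple):
    """The two maximized responses of a formulation."""

    y1: float  #: steady-state permeation rate, ug/(cm^2*s)
    y2: float  #: skin retention, mg/cm^2


def _as_point(x) -> np.ndarray:
    if isinstance(x, FormulationVariables):
        return x.as_array()
    return np.asarray(x, float)


def objective_vector(
    x, model_y1: QuadraticModel, model_y2: QuadraticModel
) -> ObjectiveVector:
    """Component-wise model predictions at ``x`` (no scalarization)."""
    p = _as_point(x)
    return ObjectiveVector(y1=float(model_y1.predict(p)), y2=float(model_y2.predict(p)))


def make_objective_function(
    model_y1: QuadraticModel, model_y2: QuadraticModel
) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized (n, 3) -> (n, 2) objective map used by the optimizers."""

    def objectives(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return np.column_stack([model_y1.predict(X), model_y2.predict(X)])

    return objectives


def surfactant_percent(x) -> float:
    """Mass percent of mixed surfactant in the finished microemulsion.

    With 5% lidocaine and ``100·x3`` % water, oil + surfactant occupy
    ``95 − 100·x3`` percent, of which the surfactant share is ``x1``.
    """
    p = _as_point(x)
    return float(p[0] * (95.0 - 100.0 * p[2]))


@dataclass(frozen=True)
class Composition:
    """Complete recipe of a 5% lidocaine microemulsion, percent by mass."""

    lidocaine: float
    water: float
    rh40: float
    span80: float
    ol: float
    ala: float
    la: float
    ves: float

    def as_dict(self) -> dict[str, float]:
        return {
            "lidocaine": self.lidocaine,
            "water": self.water,
            "RH40": self.rh40,
            "Span80": self.span80,
            "OL": self.ol,
            "ALA": self.ala,
            "LA": self.la,
            "VES": self.ves,
        }

    @property
    def total(self) -> float:
        return float(sum(self.as_dict().values()))

    @property
    def surfactant(self) -> float:
        """RH40 + Span 80, percent by mass."""
        return self.rh40 + self.span80


def composition(x) -> Composition:
    """Map decision variables to the full recipe.

    Mass balance: lidocaine 5, water ``100·x3``, oil+surfactant the rest.
    Within the oil phase: VES is 1/7 (mixed-oil:VES = 6:1); the mixed oil
    splits into OL and ALA+LA in ratio ``x2``; ALA:LA = 1:4.  Within the
    surfactant: RH40:Span80 = 5:1.  Components sum to 100 exactly.
    """
    p = _as_point(x)
    x1, x2, x3 = p
    os_total = 95.0 - 100.0 * x3
    s = x1 * os_total
    o = (1.0 - x1) * os_total
    ves = o / 7.0
    mixed = 6.0 * o / 7.0
    ol = mixed * x2 / (1.0 + x2)
    ala = mixed / (5.0 * (1.0 + x2))
    la = 4.0 * mixed / (5.0 * (1.0 + x2))
    return Composition(
        lidocaine=LIDOCAINE_PCT,
        water=100.0 * x3,
        rh40=5.0 * s / 6.0,
        span80=s / 6.0,
        ol=ol,
        ala=ala,
        la=la,
        ves=ves,
    )
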