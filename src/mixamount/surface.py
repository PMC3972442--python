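"""Response-surface evaluation over the simplex-by-amount space.

Predictions here are population-average: block effects are excluded, so a
pure-component prediction at mid amount equals that component's blending
coefficient.  The main export is the binary-blend-by-amount slice grid that
underlies the usual mixture-amount contour figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .basis import AmountFactor, ComponentSpace, TermDescriptor, build_model_matrix
from .fitting import FitResult

__all__ = ["SurfaceModel", "SurfaceGrid", "slice_grid", "find_extremum", "simplex_lattice"]


@dataclass
class SurfaceModel:
    """A coefficient model over (proportions, actual amount).

    Coefficients are on the coded-amount scale; the amount factor performs the
    coding internally, so callers work in actual units throughout.
    """

    space: ComponentSpace
    factor: AmountFactor
    terms: tuple[TermDescriptor, ...]
    coef: np.ndarray
    response: str = "response"
    units: str = ""

    def __post_init__(self) -> None:
        self.terms = tuple(self.terms)
        self.coef = np.asarray(self.coef, dtype=float)
        if len(self.coef) != len(self.terms):
            raise ValueError("one coefficient per term required")
        q = self.space.q
        for t in self.terms:
            if any(i >= q for i in t.components):
                raise ValueError(f"term {t} references unknown component (q={q})")

    @classmethod
    def from_fit(cls, fitres: FitResult, response: str = "response", units: str = "") -> "SurfaceModel":
        return cls(
            fitres.design.space,
            fitres.design.factor,
            fitres.terms,
            fitres.coef.copy(),
            response,
            units,
        )

    @classmethod
    def from_labeled(
        cls,
        space: ComponentSpace,
        factor: AmountFactor,
        coef: dict[tuple[tuple[int, ...], int], float] | Sequence[tuple[TermDescriptor, float]],
        response: str = "response",
        units: str = "",
    ) -> "SurfaceModel":
        if isinstance(coef, dict):
            items = [(TermDescriptor(c, a), v) for (c, a), v in coef.items()]
        else:
            items = list(coef)
        terms = tuple(t for t, _ in items)
        values = np.array([v for _, v in items], dtype=float)
        return cls(space, factor, terms, values, response, units)

    def predict(self, proportions, amount):
        """Predicted response at (proportions, actual amount); vectorized over rows."""
        P = np.atleast_2d(np.asarray(proportions, dtype=float))
        c = self.factor.code(np.asarray(amount, dtype=float))
        c = np.broadcast_to(np.atleast_1d(c), (P.shape[0],))
        X = build_model_matrix((P, c), self.terms, space=self.space)
        out = X @ self.coef
        return float(out[0]) if np.ndim(proportions) == 1 and np.ndim(amount) == 0 else out


@dataclass
class SurfaceGrid:
    """A binary-blend slice: fraction of component A against actual amount."""

    component_a: str
    component_b: str
    fractions: np.ndarray  # blend fraction t of component A, in [0, 1]
    amounts: np.ndarray  # actual units
    values: np.ndarray  # (len(fractions), len(amounts))
    response: str
    units: str

    def to_frame(self):
        import pandas as pd

        tt, aa = np.meshgrid(self.fractions, self.amounts, indexing="ij")
        return pd.DataFrame(
            {
                f"{self.component_a}_fraction": tt.ravel(),
                "amount": aa.ravel(),
                "prediction": self.values.ravel(),
            }
        )


def slice_grid(
    model: SurfaceModel,
    component_pair: tuple[str, str],
    amount_range: tuple[float, float] | None = None,
    resolution: int = 21,
    amount_resolution: int | None = None,
) -> SurfaceGrid:
    """Evaluate the surface on a binary-blend x amount grid.

    Axis 1 sweeps the blend fraction t in [0, 1] with proportions t on the
    first component, 1 - t on the second and 0 elsewhere; axis 2 sweeps the
    actual amount across the factor range.
    """
    a, b = component_pair
    if a == b:
        raise ValueError("component pair must name two different components")
    ia, ib = model.space.index(a), model.space.index(b)
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    if amount_range is None:
        amount_range = (model.factor.low, model.factor.high)
    n_amt = amount_resolution or resolution
    t = np.linspace(0.0, 1.0, resolution)
    amounts = np.linspace(amount_range[0], amount_range[1], n_amt)
    P = np.zeros((resolution, model.space.q))
    P[:, ia] = t
    P[:, ib] = 1.0 - t
    values = np.empty((resolution, n_amt))
    for j, amt in enumerate(amounts):
        values[:, j] = model.predict(P, amt)
    return SurfaceGrid(a, b, t, amounts, values, model.response, model.units)


def simplex_lattice(q: int, resolution: int) -> np.ndarray:
    """All proportion vectors with entries k/(resolution-1) summing to 1."""
    m = resolution - 1
    pts = []
    for cuts in combinations(range(m + q - 1), q - 1):
        counts = np.diff((-1,) + cuts + (m + q - 1,)) - 1
        pts.append(counts / m)
    return np.array(pts)


def find_extremum(
    model: SurfaceModel,
    sense: str = "max",
    resolution: int = 11,
    amount_resolution: int = 11,
) -> tuple[np.ndarray, float, float]:
    """Grid-search extremum over a simplex lattice crossed with an amount grid.

    Returns (proportions, amount, value).  Ties break deterministically toward
    the lexicographically first grid point.
    """
    if sense not in ("min", "max"):
        raise ValueError("sense must be 'min' or 'max'")
    if resolution < 11:
        raise ValueError("resolution must be >= 11 for a meaningful search")
    P = simplex_lattice(model.space.q, resolution)
    amounts = np.linspace(model.factor.low, model.factor.high, amount_resolution)
    best_val = None
    best = None
    for amt in amounts:
        vals = model.predict(P, amt)
        i = int(np.argmin(vals) if sense == "min" else np.argmax(vals))
        v = float(vals[i])
        better = best_val is None or (v < best_val if sense == "min" else v > best_val)
        if better:
            best_val = v
            best = (P[i].copy(), float(amt))
    return best[0], best[1], best_val
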