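"""Scheffé mixture basis crossed with a coded amount factor.

A mixture experiment varies the *proportions* ``x_1 … x_q`` of the components
of a blend, subject to the simplex constraint ``sum_i x_i = 1``.  Scheffé
polynomials are the canonical no-intercept bases for such data: the linear
form ``sum_i beta_i x_i`` (whose coefficients are the predicted responses of
the pure components, the "blending" coefficients) plus, at quadratic order,
the pairwise products ``x_i x_j`` that capture synergistic/antagonistic
blending.  A *mixture-amount* experiment additionally varies the total amount
(dose) of the blend; here the amount enters as a coded factor ``c in [-1, 1]``
and every mixture term is crossed with powers of ``c``.

This module defines the simplex/amount domain types, the crossed term set,
and the model-matrix construction used by the design and fitting layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ComponentSpace",
    "AmountFactor",
    "TermDescriptor",
    "ModelSpec",
    "enumerate_terms",
    "n_crossed_terms",
    "build_model_matrix",
    "code_amount",
    "decode_amount",
    "amount_range_from_composition",
]

#: tolerance on the simplex sum constraint
SIMPLEX_ATOL = 1e-9


@dataclass(frozen=True)
class ComponentSpace:
    """The mixture simplex: named components with optional proportion bounds."""

    names: tuple[str, ...]
    lower: tuple[float, ...] | None = None
    upper: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        q = len(names)
        if q < 2:
            raise ValueError(f"a mixture needs at least 2 components, got {q}")
        if len(set(names)) != q:
            raise ValueError("component names must be unique")
        lower = tuple(self.lower) if self.lower is not None else (0.0,) * q
        upper = tuple(self.upper) if self.upper is not None else (1.0,) * q
        if len(lower) != q or len(upper) != q:
            raise ValueError("bounds must have one entry per component")
        for lo, hi in zip(lower, upper):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"bounds must satisfy 0 <= lower <= upper <= 1, got ({lo}, {hi})")
        if sum(lower) > 1.0 + SIMPLEX_ATOL or sum(upper) < 1.0 - SIMPLEX_ATOL:
            raise ValueError("bounds leave no feasible mixture (need sum lower <= 1 <= sum upper)")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def q(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def validate_point(self, proportions: Sequence[float], atol: float = SIMPLEX_ATOL) -> np.ndarray:
        """Check a proportion vector against the simplex invariants; return it as an array."""
        x = np.asarray(proportions, dtype=float)
        if x.shape != (self.q,):
            raise ValueError(f"expected {self.q} proportions, got shape {x.shape}")
        if np.any(x < -atol) or np.any(x > 1 + atol):
            raise ValueError(f"proportions must lie in [0, 1]: {x}")
        if abs(x.sum() - 1.0) > atol:
            raise ValueError(f"proportions must sum to 1 (got {x.sum():.12g}): {x}")
        return x

    @property
    def centroid(self) -> np.ndarray:
        return np.full(self.q, 1.0 / self.q)


@dataclass(frozen=True)
class AmountFactor:
    """Total-amount factor with an affine coding onto [-1, +1].

    ``low`` and ``high`` are in actual units (e.g. mg per 100 g diet);
    ``code(low) = -1`` and ``code(high) = +1``.
    """

    name: str
    low: float
    high: float
    units: str = "mg/100g"

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"need low < high, got ({self.low}, {self.high})")

    @property
    def mid(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, actual):
        return (np.asarray(actual, dtype=float) - self.mid) / self.half_range

    def decode(self, coded):
        return np.asarray(coded, dtype=float) * self.half_range + self.mid

    def contains(self, actual) -> bool:
        a = np.asarray(actual, dtype=float)
        return bool(np.all((a >= self.low) & (a <= self.high)))


def code_amount(actual, factor: AmountFactor):
    """Code an actual amount onto [-1, +1]; warns (but proceeds) on extrapolation."""
    if not factor.contains(actual):
        warnings.warn(
            f"amount {actual} outside design range [{factor.low}, {factor.high}]; extrapolating",
            stacklevel=2,
        )
    out = factor.code(actual)
    return float(out) if np.isscalar(actual) else out


def decode_amount(coded, factor: AmountFactor):
    out = factor.decode(coded)
    return float(out) if np.isscalar(coded) else out


def amount_range_from_composition(mean_contents: Sequence[float], multiplier: float) -> tuple[float, float]:
    """Derive the (low, high) amount range from per-component mean contents.

    The low end is the sum of the means rounded to the nearest integer
    (half away from zero, so e.g. 74.50 -> 75); the high end is ``low * multiplier``.
    """
    contents = np.asarray(mean_contents, dtype=float)
    if contents.size == 0:
        raise ValueError("mean_contents must be non-empty")
    if np.any(contents < 0):
        raise ValueError("mean contents must be non-negative")
    if not multiplier > 1:
        raise ValueError(f"multiplier must exceed 1, got {multiplier}")
    total = float(contents.sum())
    low = float(np.floor(total + 0.5)) if total >= 0 else -float(np.floor(-total + 0.5))
    return low, low * multiplier


@dataclass(frozen=True)
class TermDescriptor:
    """One crossed model term: a mixture part (1 or 2 components) times an amount power.

    ``components`` is a sorted tuple of component indices; ``amount_exp`` is the
    exponent on the coded amount.  There is never an intercept-only term — the
    mixture part is always non-empty, which is what makes the Scheffé basis a
    no-intercept basis (the intercept is implicit in the simplex constraint).
    """

    components: tuple[int, ...]
    amount_exp: int = 0

    def __post_init__(self) -> None:
        comps = tuple(sorted(self.components))
        object.__setattr__(self, "components", comps)
        if not 1 <= len(comps) <= 2:
            raise ValueError(f"mixture part must have 1 or 2 components, got {comps}")
        if len(set(comps)) != len(comps):
            raise ValueError(f"repeated component in term: {comps}")
        if self.amount_exp not in (0, 1, 2):
            raise ValueError(f"amount exponent must be 0, 1 or 2, got {self.amount_exp}")

    @property
    def is_linear_mixture(self) -> bool:
        """True for the q mandatory blending terms (single component, no amount power)."""
        return len(self.components) == 1 and self.amount_exp == 0

    def label(self, names: Sequence[str], amount_label: str = "[Conc.]") -> str:
        s = " x ".join(names[i] for i in self.components)
        if self.amount_exp == 1:
            s += f" x {amount_label}"
        elif self.amount_exp == 2:
            s += f" x {amount_label}^2"
        return s

    def value(self, proportions: np.ndarray, coded_amount) -> np.ndarray:
        P = np.atleast_2d(np.asarray(proportions, dtype=float))
        col = np.prod(P[:, list(self.components)], axis=1)
        if self.amount_exp:
            col = col * np.asarray(coded_amount, dtype=float) ** self.amount_exp
        return col


def n_crossed_terms(q: int, mixture_order: int, amount_order: int) -> int:
    """Closed-form size of the full crossing: (q + [m=2]*q(q-1)/2) * (d+1)."""
    n_mix = q + (q * (q - 1) // 2 if mixture_order == 2 else 0)
    return n_mix * (amount_order + 1)


def enumerate_terms(q: int, mixture_order: int, amount_order: int) -> list[TermDescriptor]:
    """Enumerate the full crossed term set in a fixed, reproducible order.

    Mixture parts run singles first (by component index) then pairs
    (lexicographic); within each mixture part the amount exponent increases.
    """
    if q < 2:
        raise ValueError(f"need q >= 2 components, got {q}")
    if mixture_order not in (1, 2):
        raise ValueError(f"mixture order must be 1 (linear) or 2 (quadratic), got {mixture_order}")
    if amount_order not in (0, 1, 2):
        raise ValueError(f"amount order must be 0, 1 or 2, got {amount_order}")
    parts: list[tuple[int, ...]] = [(i,) for i in range(q)]
    if mixture_order == 2:
        parts += list(combinations(range(q), 2))
    return [TermDescriptor(p, a) for p in parts for a in range(amount_order + 1)]


@dataclass(frozen=True)
class ModelSpec:
    """A crossed Scheffé-by-amount model: orders plus the (possibly reduced) term list."""

    mixture_order: int
    amount_order: int
    terms: tuple[TermDescriptor, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        if self.mixture_order not in (1, 2) or self.amount_order not in (0, 1, 2):
            raise ValueError("invalid model orders")
        if not self.terms:
            raise ValueError("a model needs at least one term")

    @classmethod
    def full(cls, q: int, mixture_order: int, amount_order: int) -> "ModelSpec":
        return cls(mixture_order, amount_order, tuple(enumerate_terms(q, mixture_order, amount_order)))

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def labels(self, names: Sequence[str]) -> list[str]:
        return [t.label(names) for t in self.terms]


def build_model_matrix(
    points: Iterable[tuple[Sequence[float], float]] | tuple[np.ndarray, np.ndarray],
    terms: Sequence[TermDescriptor],
    *,
    space: ComponentSpace | None = None,
    atol: float = SIMPLEX_ATOL,
) -> np.ndarray:
    """Model matrix for crossed Scheffé terms at mixture/amount points.

    ``points`` is either an iterable of ``(proportions, coded_amount)`` pairs or a
    pre-stacked ``(P, c)`` pair with ``P`` of shape (n, q).  Every proportion row
    must sum to 1 within ``atol`` (the simplex constraint); there is no intercept
    column.
    """
    if isinstance(points, tuple) and len(points) == 2 and np.ndim(points[0]) == 2:
        P = np.asarray(points[0], dtype=float)
        c = np.asarray(points[1], dtype=float)
    else:
        pts = list(points)
        P = np.array([np.asarray(p, dtype=float) for p, _ in pts])
        c = np.array([float(a) for _, a in pts])
    if P.ndim != 2:
        raise ValueError("proportions must form a 2-D array")
    bad = np.flatnonzero(np.abs(P.sum(axis=1) - 1.0) > atol)
    if bad.size:
        raise ValueError(f"proportion rows do not sum to 1: rows {bad.tolist()}")
    if space is not None and P.shape[1] != space.q:
        raise ValueError(f"expected {space.q} components, got {P.shape[1]}")
    cols = [t.value(P, c) for t in terms]
    return np.column_stack(cols) if cols else np.empty((P.shape[0], 0))
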