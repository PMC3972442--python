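"""Blocked mixture-amount design construction.

Builds the experiment layout used throughout the package: a D-optimally
selected set of model points on the simplex-by-amount space, augmented with
distance-spread lack-of-fit points, leverage-chosen replicates, centroid
center points, and a balanced block assignment.  Also does the degrees-of-
freedom accounting under the mixture (no-intercept) ANOVA convention.

D-optimality maximizes det(X'X), the information of the coefficient
estimates; here it is implemented as a candidate-set Fedorov point-exchange
with multiple random starts, selecting points without replacement
(replication is a separate, explicit augmentation stage).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Sequence

import numpy as np

from .basis import (
    AmountFactor,
    ComponentSpace,
    TermDescriptor,
    build_model_matrix,
    enumerate_terms,
)

__all__ = [
    "DesignPoint",
    "Design",
    "DfPartition",
    "CandidateSet",
    "generate_candidates",
    "select_d_optimal",
    "augment_lack_of_fit",
    "augment_replicates",
    "add_center_points",
    "assign_blocks",
    "df_partition",
    "build_study_design",
    "InestimableError",
]

_KEY_DECIMALS = 9

ROLES = ("model", "lack_of_fit", "replicate", "center")


class InestimableError(ValueError):
    """The requested model cannot be estimated from the design/candidates."""


@dataclass(frozen=True)
class DesignPoint:
    """One run: component proportions, actual amount, block id, and design role."""

    proportions: tuple[float, ...]
    amount: float
    block: int | None = None
    role: str = "model"

    def __post_init__(self) -> None:
        object.__setattr__(self, "proportions", tuple(float(p) for p in self.proportions))
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")

    def key(self) -> tuple:
        """Rounded (proportions, amount) identity used to group replicates."""
        return (
            tuple(round(p, _KEY_DECIMALS) for p in self.proportions),
            round(self.amount, _KEY_DECIMALS),
        )


@dataclass
class Design:
    """An ordered list of runs over a component space and amount factor."""

    points: list[DesignPoint]
    space: ComponentSpace
    factor: AmountFactor
    n_blocks: int = 1

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def proportions(self) -> np.ndarray:
        return np.array([p.proportions for p in self.points])

    @property
    def amounts(self) -> np.ndarray:
        return np.array([p.amount for p in self.points])

    @property
    def coded_amounts(self) -> np.ndarray:
        return self.factor.code(self.amounts)

    @property
    def blocks(self) -> np.ndarray:
        return np.array([0 if p.block is None else p.block for p in self.points])

    @property
    def roles(self) -> list[str]:
        return [p.role for p in self.points]

    def model_matrix(self, terms: Sequence[TermDescriptor]) -> np.ndarray:
        return build_model_matrix((self.proportions, self.coded_amounts), terms, space=self.space)

    def distinct(self) -> tuple[np.ndarray, np.ndarray]:
        """(index of first occurrence per distinct point, group id per run)."""
        seen: dict[tuple, int] = {}
        first: list[int] = []
        group = np.empty(self.n, dtype=int)
        for i, p in enumerate(self.points):
            k = p.key()
            if k not in seen:
                seen[k] = len(first)
                first.append(i)
            group[i] = seen[k]
        return np.array(first, dtype=int), group

    @property
    def n_distinct(self) -> int:
        return len(self.distinct()[0])

    def validate(self, atol: float = 1e-9) -> None:
        for i, p in enumerate(self.points):
            try:
                self.space.validate_point(p.proportions, atol=atol)
            except ValueError as exc:
                raise ValueError(f"run {i}: {exc}") from exc
            if not self.factor.contains(p.amount):
                raise ValueError(f"run {i}: amount {p.amount} outside factor range")

    def to_frame(self):
        import pandas as pd

        rows = {
            "run_id": np.arange(1, self.n + 1),
            "block": self.blocks + 1,
            "role": self.roles,
        }
        P = self.proportions
        for j, name in enumerate(self.space.names):
            rows[name] = P[:, j]
        rows["amount_actual"] = self.amounts
        rows["amount_coded"] = self.coded_amounts
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DfPartition:
    """Block / model / lack-of-fit / pure-error degrees-of-freedom accounting."""

    block: int
    model: int
    lack_of_fit: int
    pure_error: int
    total: int

    def __post_init__(self) -> None:
        parts = (self.block, self.model, self.lack_of_fit, self.pure_error)
        if any(d < 0 for d in parts):
            raise ValueError(f"negative df component in {parts}")
        if sum(parts) != self.total:
            raise ValueError(f"df partition {parts} does not sum to total {self.total}")


@dataclass
class CandidateSet:
    """Candidate (proportions, coded amount) points with a provenance tag each."""

    proportions: np.ndarray  # (m, q)
    coded_amounts: np.ndarray  # (m,)
    provenance: list[str]

    @property
    def m(self) -> int:
        return len(self.coded_amounts)

    def model_matrix(self, terms: Sequence[TermDescriptor]) -> np.ndarray:
        return build_model_matrix((self.proportions, self.coded_amounts), terms)

    def subset(self, idx: Sequence[int]) -> "CandidateSet":
        idx = np.asarray(idx, dtype=int)
        return CandidateSet(
            self.proportions[idx], self.coded_amounts[idx], [self.provenance[i] for i in idx]
        )

    def coords(self) -> np.ndarray:
        """Coded-space coordinates (proportions ⊕ coded amount) for distances."""
        return np.column_stack([self.proportions, self.coded_amounts])


def _simplex_candidates(space: ComponentSpace, kinds: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    q = space.q
    pts: list[np.ndarray] = []
    tags: list[str] = []
    if "vertex" in kinds:
        for i in range(q):
            v = np.zeros(q)
            v[i] = 1.0
            pts.append(v)
            tags.append("vertex")
    if "edge" in kinds:
        for i, j in combinations(range(q), 2):
            v = np.zeros(q)
            v[i] = v[j] = 0.5
            pts.append(v)
            tags.append("edge-midpoint")
    if "centroid" in kinds:
        pts.append(space.centroid)
        tags.append("centroid")
    if "axial" in kinds:
        # midpoint between each vertex and the overall centroid
        for i in range(q):
            v = np.full(q, 0.5 / q)
            v[i] += 0.5
            pts.append(v)
            tags.append("axial")
    if "interior" in kinds:
        # sparse interior lattice: all 2-component 25:75 blends
        for i, j in combinations(range(q), 2):
            for a in (0.25, 0.75):
                v = np.zeros(q)
                v[i], v[j] = a, 1 - a
                pts.append(v)
                tags.append("interior")
    return np.array(pts), tags


def generate_candidates(
    space: ComponentSpace,
    amount_levels: Sequence[float],
    kinds: Sequence[str] = ("vertex", "edge", "centroid", "axial"),
) -> CandidateSet:
    """Cross standard simplex candidate points with coded amount levels.

    Candidate classes: simplex vertices, binary 50:50 edge midpoints, the
    overall centroid, axial check blends (vertex-centroid midpoints) and an
    optional sparse interior lattice.
    """
    levels = np.asarray(amount_levels, dtype=float)
    if levels.size == 0:
        raise ValueError("amount_levels must be non-empty")
    if np.any(np.abs(levels) > 1 + 1e-12):
        raise ValueError("coded amount levels must lie in [-1, 1]")
    P, tags = _simplex_candidates(space, kinds)
    # de-duplicate simplex points (within rounding) while keeping order
    seen: dict[tuple, int] = {}
    keep: list[int] = []
    for i, row in enumerate(P):
        k = tuple(np.round(row, _KEY_DECIMALS))
        if k not in seen:
            seen[k] = i
            keep.append(i)
    P, tags = P[keep], [tags[i] for i in keep]
    reps = len(levels)
    allP = np.repeat(P, reps, axis=0)
    allc = np.tile(levels, len(P))
    alltags = [t for t in tags for _ in range(reps)]
    return CandidateSet(allP, allc, alltags)


def _exchange_once(
    F: np.ndarray, n_points: int, rng: np.random.Generator, ridge: float, max_iter: int = 200
) -> tuple[np.ndarray, float]:
    """One Fedorov exchange run from a random start; returns (indices, logdet)."""
    m, t = F.shape
    idx = rng.choice(m, size=n_points, replace=False)
    in_design = np.zeros(m, dtype=bool)
    in_design[idx] = True
    for _ in range(max_iter):
        X = F[in_design]
        M = X.T @ X + ridge * np.eye(t)
        Minv = np.linalg.inv(M)
        A = F @ Minv @ F.T  # m x m: d(x_i, x_j) for all candidate pairs
        d = np.diag(A)
        ins = np.flatnonzero(in_design)
        outs = np.flatnonzero(~in_design)
        if outs.size == 0:
            break
        # det ratio for swapping out i, in j: (1 + d_j)(1 - d_i) + d_ij^2
        ratio = (1.0 + d[outs])[None, :] * (1.0 - d[ins])[:, None] + A[np.ix_(ins, outs)] ** 2
        best = np.unravel_index(np.argmax(ratio), ratio.shape)
        if ratio[best] <= 1.0 + 1e-10:
            break
        in_design[ins[best[0]]] = False
        in_design[outs[best[1]]] = True
    X = F[in_design]
    sign, logdet = np.linalg.slogdet(X.T @ X)
    return np.flatnonzero(in_design), (logdet if sign > 0 else -np.inf)


def select_d_optimal(
    candidates: CandidateSet,
    terms: Sequence[TermDescriptor],
    n_points: int,
    factor: AmountFactor,
    seed: int = 0,
    n_starts: int = 10,
    space: ComponentSpace | None = None,
) -> Design:
    """D-optimal subset of the candidates by multi-start Fedorov exchange.

    At each iteration the single swap (design point out, candidate in) with the
    largest det(X'X) gain is applied; the run stops when no swap improves the
    determinant by more than 1e-10 relative.  The best of ``n_starts`` random
    starts is kept.  Points are selected without replacement.
    """
    t = len(terms)
    if n_points < t:
        raise InestimableError(f"need at least {t} points for {t} terms, got {n_points}")
    if candidates.m < n_points:
        raise ValueError(f"only {candidates.m} candidates for {n_points} points")
    F = candidates.model_matrix(terms)
    scale = np.median(np.sum(F**2, axis=1)) or 1.0
    ridge = 1e-8 * scale
    rng = np.random.default_rng(seed)
    best_idx, best_logdet = None, -np.inf
    for _ in range(max(1, n_starts)):
        idx, logdet = _exchange_once(F, n_points, rng, ridge)
        if logdet > best_logdet:
            best_idx, best_logdet = idx, logdet
    if best_idx is None or not np.isfinite(best_logdet):
        raise InestimableError("information matrix singular for every start; model not estimable")
    if space is None:
        space = ComponentSpace(tuple(f"x{i + 1}" for i in range(candidates.proportions.shape[1])))
    points = [
        DesignPoint(
            tuple(candidates.proportions[i]),
            float(factor.decode(candidates.coded_amounts[i])),
            role="model",
        )
        for i in sorted(best_idx)
    ]
    return Design(points, space, factor)


def augment_lack_of_fit(
    design: Design, candidates: CandidateSet, n: int, seed: int = 0
) -> Design:
    """Add ``n`` lack-of-fit points by greedy maximin distance in coded space."""
    if n == 0:
        return design
    coords = np.column_stack([design.proportions, design.coded_amounts])
    cand = candidates.coords()
    # drop candidates already present in the design
    dist0 = np.linalg.norm(cand[:, None, :] - coords[None, :, :], axis=2)
    available = np.flatnonzero(dist0.min(axis=1) > 1e-9)
    if available.size < n:
        raise ValueError(f"only {available.size} distinct candidates available, need {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(available)  # seeded tie-break order
    chosen: list[int] = []
    mind = dist0.min(axis=1)
    for _ in range(n):
        best = order[int(np.argmax(mind[order]))]
        chosen.append(int(best))
        order = order[order != best]
        d_new = np.linalg.norm(cand - cand[best], axis=1)
        mind = np.minimum(mind, d_new)
    new_points = [
        DesignPoint(
            tuple(candidates.proportions[i]),
            float(design.factor.decode(candidates.coded_amounts[i])),
            role="lack_of_fit",
        )
        for i in chosen
    ]
    return Design(design.points + new_points, design.space, design.factor, design.n_blocks)


def augment_replicates(
    design: Design, n: int, terms: Sequence[TermDescriptor], seed: int = 0
) -> Design:
    """Duplicate the ``n`` highest-leverage distinct points (exact copies, role=replicate).

    Leverage is computed under the design model on the distinct points; ties are
    broken by a seeded shuffle; if ``n`` exceeds the distinct count the ranking
    cycles.
    """
    if n == 0:
        return design
    first, _ = design.distinct()
    P = design.proportions[first]
    c = design.coded_amounts[first]
    X = build_model_matrix((P, c), terms)
    Q, _ = np.linalg.qr(X)
    h = np.sum(Q**2, axis=1)
    rng = np.random.default_rng(seed)
    jitter = rng.permutation(len(first))  # tie-break: random secondary key
    order = np.lexsort((jitter, -h))
    picks = [first[order[i % len(first)]] for i in range(n)]
    new_points = [
        DesignPoint(design.points[i].proportions, design.points[i].amount, role="replicate")
        for i in picks
    ]
    return Design(design.points + new_points, design.space, design.factor, design.n_blocks)


def add_center_points(design: Design, n: int) -> Design:
    """Append ``n`` centroid runs (equal proportions, mid amount), role=center."""
    if n < 0:
        raise ValueError("n must be >= 0")
    centroid = tuple(design.space.centroid)
    mid = design.factor.mid
    new_points = [DesignPoint(centroid, mid, role="center") for _ in range(n)]
    return Design(design.points + new_points, design.space, design.factor, design.n_blocks)


def assign_blocks(design: Design, n_blocks: int, seed: int = 0) -> Design:
    """Assign runs to blocks: sizes differ by at most 1, replicates spread across blocks.

    Runs sharing a distinct point are placed in different blocks where capacity
    allows, so replicate pairs contribute pure error both within and across
    blocks.  Assignment is seeded and reproducible.
    """
    N = design.n
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if n_blocks > N:
        raise ValueError(f"cannot split {N} runs into {n_blocks} blocks")
    base, extra = divmod(N, n_blocks)
    capacity = np.array([base + (1 if b < extra else 0) for b in range(n_blocks)], dtype=int)
    rng = np.random.default_rng(seed)
    _, group = design.distinct()
    groups: dict[int, list[int]] = {}
    for i, g in enumerate(group):
        groups.setdefault(int(g), []).append(i)
    order = sorted(groups, key=lambda g: (-len(groups[g]), rng.random()))
    assignment = np.full(N, -1, dtype=int)
    for g in order:
        members = groups[g]
        used: set[int] = set()
        for i in members:
            # prefer blocks not yet holding this point, then max remaining capacity
            cand = sorted(
                range(n_blocks),
                key=lambda b: (b in used, -capacity[b], rng.random()),
            )
            b = next(b for b in cand if capacity[b] > 0)
            assignment[i] = b
            capacity[b] -= 1
            used.add(b)
    points = [replace(p, block=int(b)) for p, b in zip(design.points, assignment)]
    return Design(points, design.space, design.factor, n_blocks)


def df_partition(design: Design, terms: Sequence[TermDescriptor]) -> DfPartition:
    """Degrees-of-freedom accounting under the mixture no-intercept convention.

    block df = n_blocks - 1; model df = #terms - 1 (one df absorbed by the
    blending constraint); lack-of-fit df = #distinct points - #terms; pure
    error is the remainder of N - 1.  Block effects consume replicate df, so
    pure error is generally below the naive within-point count.
    """
    first, _ = design.distinct()
    m = len(first)
    t = len(terms)
    X = build_model_matrix(
        (design.proportions[first], design.coded_amounts[first]), terms
    )
    s = np.linalg.svd(X, compute_uv=False)
    if s.size == 0 or s[-1] <= max(X.shape) * np.finfo(float).eps * s[0]:
        raise InestimableError("information matrix on distinct points is singular")
    if m < t:
        raise InestimableError(f"{m} distinct points cannot estimate {t} terms")
    N = design.n
    block = design.n_blocks - 1
    model = t - 1
    lof = m - t
    pure = (N - 1) - block - model - lof
    if pure < 0:
        raise InestimableError(f"pure-error df negative ({pure}); design too small for blocks/terms")
    return DfPartition(block, model, lof, pure, N - 1)


def build_study_design(
    space: ComponentSpace,
    factor: AmountFactor,
    terms: Sequence[TermDescriptor] | None = None,
    n_model: int = 45,
    n_lof: int = 5,
    n_replicates: int = 45,
    n_centers: int = 5,
    n_blocks: int = 5,
    seed: int = 0,
    amount_levels: Sequence[float] = (-1.0, 0.0, 1.0),
    candidate_kinds: Sequence[str] = ("vertex", "edge", "centroid", "axial"),
    reserve_centroid: bool = True,
    n_starts: int = 10,
) -> Design:
    """Build the full blocked study design in one call.

    Stages: candidate generation -> D-optimal model points -> maximin
    lack-of-fit points -> leverage-ranked replicates -> centroid center points
    -> balanced block assignment.  With ``reserve_centroid`` the centroid at
    mid-amount is withheld from the model/lack-of-fit pools so the center-point
    stage contributes exactly one new distinct point.
    """
    if terms is None:
        terms = enumerate_terms(space.q, 2, 2)
    cands = generate_candidates(space, amount_levels, candidate_kinds)
    if reserve_centroid:
        centroid = space.centroid
        is_center = (
            np.all(np.abs(cands.proportions - centroid) < 1e-12, axis=1)
            & (np.abs(cands.coded_amounts) < 1e-12)
        )
        cands = cands.subset(np.flatnonzero(~is_center))
    seeds = np.random.SeedSequence(seed).generate_state(4) & 0x7FFFFFFF
    d = select_d_optimal(
        cands, terms, n_model, factor, seed=int(seeds[0]), n_starts=n_starts, space=space
    )
    d = augment_lack_of_fit(d, cands, n_lof, seed=int(seeds[1]))
    d = augment_replicates(d, n_replicates, terms, seed=int(seeds[2]))
    d = add_center_points(d, n_centers)
    d = assign_blocks(d, n_blocks, seed=int(seeds[3]))
    return d
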