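"""No-intercept least squares for crossed Scheffé models, with mixture-convention ANOVA.

The response model is ``y = X beta + Z gamma + e`` where ``X`` is the Scheffé
crossed model matrix (no intercept: the simplex constraint makes the intercept
implicit in the linear blending terms) and ``Z`` is a sum-to-zero coding of
fixed block effects.  The ANOVA follows the mixture convention:

* Model df = (#terms) - 1, one df being absorbed by the blending constraint;
  the Model sum of squares is the reduction in SSE over the mean+blocks fit.
* The "Linear Mixture" row is a joint F test of equality of the q blending
  coefficients (q - 1 contrasts), computed after block adjustment.
* Residual variation splits into lack of fit (between distinct design points)
  and pure error (replicate scatter after block adjustment); their F ratio
  tests model adequacy.

Fits are solved by QR, so results are deterministic and bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, stats

from .basis import ModelSpec, TermDescriptor
from .design import Design, InestimableError

__all__ = [
    "FitResult",
    "AnovaRow",
    "AnovaTable",
    "R2Stats",
    "OrderTrace",
    "ModelSelectionTrace",
    "block_columns",
    "fit",
    "anova",
    "lack_of_fit",
    "r2_stats",
    "select_model_order",
    "backward_eliminate",
]

_RCOND = 1e-10


def block_columns(blocks: np.ndarray, n_blocks: int) -> np.ndarray:
    """Sum-to-zero block coding: n x (n_blocks - 1) matrix.

    Block b < last gets indicator column b; the last block carries -1 in every
    column, so the block effects sum to zero over blocks.
    """
    n = len(blocks)
    Z = np.zeros((n, max(n_blocks - 1, 0)))
    for j in range(n_blocks - 1):
        Z[blocks == j, j] = 1.0
    Z[blocks == n_blocks - 1, :] = -1.0
    return Z


def _solve_ls(W: np.ndarray, y: np.ndarray, labels: Sequence[str]):
    """QR least squares with an explicit rank check naming offending columns."""
    n, p = W.shape
    if p == 0:
        return np.empty(0), np.empty((0, 0)), np.zeros(n)
    _, R, piv = linalg.qr(W, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > _RCOND * diag[0])) if diag.size else 0
    if rank < p:
        bad = [labels[i] for i in piv[rank:]]
        raise InestimableError(f"model matrix is rank deficient; aliased columns: {bad}")
    Q, R = np.linalg.qr(W)
    beta = linalg.solve_triangular(R, Q.T @ y)
    Rinv = linalg.solve_triangular(R, np.eye(p))
    cov_unscaled = Rinv @ Rinv.T
    hat = np.sum(Q**2, axis=1)
    return beta, cov_unscaled, hat


@dataclass
class FitResult:
    """A fitted crossed Scheffé model on a design.

    ``coef``/``se`` are per term (response units); ``block_effects`` has one
    entry per block and sums to zero.  ``cov_unscaled`` is (W'W)^-1 for the
    combined [terms | blocks] matrix, ``hat`` its leverage diagonal.
    """

    design: Design
    terms: tuple[TermDescriptor, ...]
    y: np.ndarray
    coef: np.ndarray
    se: np.ndarray
    block_effects: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    hat: np.ndarray
    sigma2: float
    sse: float
    df_resid: int
    cov_unscaled: np.ndarray
    W: np.ndarray
    beta_full: np.ndarray

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_params(self) -> int:
        return self.W.shape[1]

    @property
    def labels(self) -> list[str]:
        return [t.label(self.design.space.names) for t in self.terms]

    def predict_terms(self) -> np.ndarray:
        """Population-average predictions (block effects excluded)."""
        return self.W[:, : len(self.terms)] @ self.coef

    def coef_table(self):
        import pandas as pd

        t = len(self.terms)
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = self.coef / self.se
        return pd.DataFrame(
            {
                "term": self.labels,
                "estimate": self.coef,
                "se": self.se,
                "t": tval,
                "p": 2 * stats.t.sf(np.abs(tval), self.df_resid) if self.df_resid > 0 else np.nan,
            }
        )

    def confint(self, level: float = 0.95) -> np.ndarray:
        tcrit = stats.t.ppf(0.5 + level / 2, self.df_resid)
        return np.column_stack([self.coef - tcrit * self.se, self.coef + tcrit * self.se])


def fit(design: Design, y: Sequence[float], terms: Sequence[TermDescriptor]) -> FitResult:
    """Least-squares fit of the crossed terms plus sum-to-zero block effects."""
    y = np.asarray(y, dtype=float)
    if y.shape != (design.n,):
        raise ValueError(f"response length {y.shape} does not match {design.n} runs")
    terms = tuple(terms)
    X = design.model_matrix(terms)
    Z = block_columns(design.blocks, design.n_blocks)
    W = np.column_stack([X, Z]) if Z.shape[1] else X
    labels = [t.label(design.space.names) for t in terms] + [
        f"block[{b + 1}]" for b in range(design.n_blocks - 1)
    ]
    beta, cov_unscaled, hat = _solve_ls(W, y, labels)
    fitted = W @ beta
    resid = y - fitted
    df_resid = design.n - W.shape[1]
    sse = float(resid @ resid)
    if sse <= 1e-18 * max(1.0, float(y @ y)):
        sse = 0.0  # numerically perfect fit
    sigma2 = sse / df_resid if df_resid > 0 else 0.0
    t = len(terms)
    se = np.sqrt(np.maximum(np.diag(cov_unscaled)[:t], 0) * sigma2)
    gamma = beta[t:]
    block_effects = np.append(gamma, -gamma.sum()) if design.n_blocks > 1 else np.zeros(1)
    return FitResult(
        design=design,
        terms=terms,
        y=y,
        coef=beta[:t].copy(),
        se=se,
        block_effects=block_effects,
        fitted=fitted,
        residuals=resid,
        hat=hat,
        sigma2=sigma2,
        sse=sse,
        df_resid=df_resid,
        cov_unscaled=cov_unscaled,
        W=W,
        beta_full=beta,
    )


@dataclass(frozen=True)
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float | None
    F: float | None
    p: float | None


@dataclass
class R2Stats:
    r2: float | None
    adj_r2: float | None
    pred_r2: float | None
    press: float | None


@dataclass
class AnovaTable:
    rows: list[AnovaRow]
    r2: R2Stats
    lof_available: bool = True

    def row(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    @property
    def model_p(self) -> float:
        return self.row("Model").p

    @property
    def lof_p(self) -> float | None:
        return self.row("Lack of Fit").p if self.lof_available else None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([r.__dict__ for r in self.rows])


def _sse_of(W: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """SSE and residual df of an auxiliary least-squares fit (rank aware)."""
    if W.size == 0:
        return float(y @ y), len(y)
    beta, res, rank, _ = np.linalg.lstsq(W, y, rcond=None)
    resid = y - W @ beta
    return float(resid @ resid), len(y) - rank


def _blocks_only_sse(fitres: FitResult) -> tuple[float, int]:
    design = fitres.design
    Z = block_columns(design.blocks, design.n_blocks)
    W0 = np.column_stack([np.ones(design.n), Z]) if Z.shape[1] else np.ones((design.n, 1))
    return _sse_of(W0, fitres.y)


def lack_of_fit(fitres: FitResult) -> tuple[float, int, float, int]:
    """(SS_lof, df_lof, SS_pe, df_pe) for the fitted model.

    Pure error is the SSE of the saturated-in-distinct-points model with block
    effects; lack of fit is the remainder of the model's residual.  This is
    the partition under which block effects consume replicate df.
    """
    design = fitres.design
    first, group = design.distinct()
    D = np.zeros((design.n, len(first)))
    D[np.arange(design.n), group] = 1.0
    Z = block_columns(design.blocks, design.n_blocks)
    Wsat = np.column_stack([D, Z]) if Z.shape[1] else D
    ss_pe, df_pe = _sse_of(Wsat, fitres.y)
    ss_lof = max(fitres.sse - ss_pe, 0.0)
    df_lof = fitres.df_resid - df_pe
    return ss_lof, df_lof, ss_pe, df_pe


def _linear_mixture_ss(fitres: FitResult) -> tuple[float, int]:
    """Joint SS for equality of the q blending coefficients (q-1 contrasts)."""
    q = fitres.design.space.q
    lin = [i for i, t in enumerate(fitres.terms) if t.is_linear_mixture]
    if len(lin) != q:
        raise InestimableError("model does not contain all q linear blending terms")
    p = fitres.n_params
    C = np.zeros((q - 1, p))
    for r in range(q - 1):
        C[r, lin[r]] = 1.0
        C[r, lin[r + 1]] = -1.0
    cb = C @ fitres.beta_full
    mid = C @ fitres.cov_unscaled @ C.T
    ss = float(cb @ np.linalg.solve(mid, cb))
    return ss, q - 1


def _partial_ss(fitres: FitResult, idx: int) -> float:
    """Type-III SS of a single-column term: b_j^2 / (W'W)^-1_jj."""
    g = fitres.cov_unscaled[idx, idx]
    return float(fitres.beta_full[idx] ** 2 / g)


#: sums of squares below this are treated as exact zeros (noiseless data)
_SS_TINY = 1e-10


def _f_p(ss: float, df: int, sigma2: float, df_resid: int) -> tuple[float, float, float]:
    if df <= 0 or df_resid <= 0:
        return np.nan, np.nan, np.nan
    ms = ss / df
    if sigma2 <= 0:
        # perfect fit: any real extra SS is infinitely significant, none is null
        return (ms, np.inf, 0.0) if ss > _SS_TINY else (ms, 0.0, 1.0)
    F = ms / sigma2
    return ms, F, float(stats.f.sf(F, df, df_resid))


def _lof_f_p(ss_lof: float, df_lof: int, ss_pe: float, df_pe: int) -> tuple[float | None, float | None]:
    """Lack-of-fit F and p; None when no pure error is available."""
    if df_pe <= 0 or df_lof <= 0:
        return None, None
    ms_pe = ss_pe / df_pe
    ms_lof = ss_lof / df_lof
    if ms_pe > 0:
        F = ms_lof / ms_pe
        return F, float(stats.f.sf(F, df_lof, df_pe))
    return (np.inf, 0.0) if ss_lof > _SS_TINY else (0.0, 1.0)


def anova(fitres: FitResult) -> AnovaTable:
    """Mixture-convention ANOVA: Model, Linear Mixture, per-term partial F, LOF, pure error."""
    sse0, _ = _blocks_only_sse(fitres)
    t = len(fitres.terms)
    ss_model = max(sse0 - fitres.sse, 0.0)
    df_model = t - 1
    rows: list[AnovaRow] = []
    ms, F, p = _f_p(ss_model, df_model, fitres.sigma2, fitres.df_resid)
    rows.append(AnovaRow("Model", df_model, ss_model, ms, F, p))
    ss_lm, df_lm = _linear_mixture_ss(fitres)
    ms, F, p = _f_p(ss_lm, df_lm, fitres.sigma2, fitres.df_resid)
    rows.append(AnovaRow("Linear Mixture", df_lm, ss_lm, ms, F, p))
    names = fitres.design.space.names
    for i, term in enumerate(fitres.terms):
        if term.is_linear_mixture:
            continue
        ss = _partial_ss(fitres, i)
        ms, F, p = _f_p(ss, 1, fitres.sigma2, fitres.df_resid)
        rows.append(AnovaRow(term.label(names), 1, ss, ms, F, p))
    ss_lof, df_lof, ss_pe, df_pe = lack_of_fit(fitres)
    F_lof, p_lof = _lof_f_p(ss_lof, df_lof, ss_pe, df_pe)
    lof_available = F_lof is not None
    if lof_available:
        rows.append(AnovaRow("Lack of Fit", df_lof, ss_lof, ss_lof / df_lof, F_lof, p_lof))
        rows.append(AnovaRow("Pure Error", df_pe, ss_pe, ss_pe / df_pe, None, None))
    else:
        rows.append(AnovaRow("Lack of Fit", max(df_lof, 0), ss_lof, None, None, None))
        rows.append(AnovaRow("Pure Error", max(df_pe, 0), ss_pe, None, None, None))
    return AnovaTable(rows, r2_stats(fitres), lof_available)


def r2_stats(fitres: FitResult) -> R2Stats:
    """R², adjusted R² and predicted R² against the block-corrected total SS.

    PRESS is the leave-one-out prediction error sum, computed from the hat
    diagonal; predicted R² = 1 - PRESS/SST.
    """
    sst, df_t = _blocks_only_sse(fitres)
    if sst <= 0:
        return R2Stats(None, None, None, None)
    r2 = 1.0 - fitres.sse / sst
    adj = (
        1.0 - (fitres.sse / fitres.df_resid) / (sst / df_t)
        if fitres.df_resid > 0
        else None
    )
    one_minus_h = 1.0 - fitres.hat
    if np.any(one_minus_h <= 1e-12):
        press = None
        pred = None
    else:
        press = float(np.sum((fitres.residuals / one_minus_h) ** 2))
        pred = 1.0 - press / sst
    return R2Stats(r2, adj, pred, press)


@dataclass
class OrderTrace:
    mixture_order: int
    amount_order: int
    n_terms: int
    seq_f: float | None
    seq_p: float | None
    lof_p: float | None
    chosen: bool = False


@dataclass
class ModelSelectionTrace:
    orders: list[OrderTrace]
    chosen: ModelSpec
    fit: FitResult
    fallback: bool = False


def _order_ladder(max_mixture_order: int, max_amount_order: int) -> list[tuple[int, int]]:
    # nested chain: mixture order raised before amount order
    full = [(1, 1), (2, 1), (2, 2)] if max_amount_order >= 1 else [(1, 0), (2, 0)]
    return [
        (m, d) for m, d in full if m <= max_mixture_order and d <= max_amount_order
    ]


def select_model_order(
    design: Design,
    y: Sequence[float],
    max_mixture_order: int = 2,
    max_amount_order: int = 2,
    alpha: float = 0.05,
) -> ModelSelectionTrace:
    """Choose the polynomial order by sequential F tests plus the lack-of-fit gate.

    Walks the nested order ladder upward; at each step the block of newly added
    terms is tested with a sequential F against the larger model's MSE.  The
    chosen model is the highest order whose added terms are significant
    (p < alpha) and whose lack-of-fit p >= alpha; if no order qualifies the
    lowest order is returned with ``fallback=True``.
    """
    y = np.asarray(y, dtype=float)
    ladder = _order_ladder(max_mixture_order, max_amount_order)
    fits: list[FitResult] = []
    traces: list[OrderTrace] = []
    prev_sse: float | None = None
    prev_t = 1  # mean absorbed by blending constraint
    for m, d in ladder:
        spec = ModelSpec.full(design.space.q, m, d)
        f = fit(design, y, spec.terms)
        ss_lof, df_lof, ss_pe, df_pe = lack_of_fit(f)
        _, p_lof = _lof_f_p(ss_lof, df_lof, ss_pe, df_pe)
        if prev_sse is None:
            sse0, _ = _blocks_only_sse(f)
            ss_add = sse0 - f.sse
        else:
            ss_add = prev_sse - f.sse
        df_add = len(spec.terms) - prev_t
        _, F_add, p_add = _f_p(max(ss_add, 0.0), df_add, f.sigma2, f.df_resid)
        traces.append(OrderTrace(m, d, len(spec.terms), F_add, p_add, p_lof))
        fits.append(f)
        prev_sse, prev_t = f.sse, len(spec.terms)
    chosen_idx = None
    for k in range(len(ladder) - 1, -1, -1):
        tr = traces[k]
        ok_add = tr.seq_p is not None and tr.seq_p < alpha
        ok_lof = tr.lof_p is None or tr.lof_p >= alpha
        if ok_add and ok_lof:
            chosen_idx = k
            break
    fallback = chosen_idx is None
    if fallback:
        chosen_idx = 0
    traces[chosen_idx].chosen = True
    m, d = ladder[chosen_idx]
    spec = ModelSpec.full(design.space.q, m, d)
    return ModelSelectionTrace(traces, spec, fits[chosen_idx], fallback)


def backward_eliminate(
    fitres: FitResult,
    alpha_out: float = 0.10,
    keep_linear_mixture: bool = True,
) -> tuple[FitResult, list[tuple[str, float]]]:
    """Backward elimination of non-mandatory terms by partial-F p-value.

    Each round refits and removes the eligible term with the largest partial-F
    p exceeding ``alpha_out``.  Linear blending terms (and block effects) are
    never removed when ``keep_linear_mixture`` is set.  Returns the reduced fit
    and the removal trace as (label, p) pairs.
    """
    current = fitres
    removed: list[tuple[str, float]] = []
    while True:
        eligible = [
            i
            for i, t in enumerate(current.terms)
            if not (keep_linear_mixture and t.is_linear_mixture)
        ]
        if not eligible or current.df_resid <= 0:
            break
        pvals = {}
        for i in eligible:
            ss = _partial_ss(current, i)
            _, _, p = _f_p(ss, 1, current.sigma2, current.df_resid)
            pvals[i] = p
        worst = max(eligible, key=lambda i: -1.0 if np.isnan(pvals[i]) else pvals[i])
        if np.isnan(pvals[worst]) or not (pvals[worst] > alpha_out):
            break
        label = current.terms[worst].label(current.design.space.names)
        removed.append((label, pvals[worst]))
        new_terms = tuple(t for j, t in enumerate(current.terms) if j != worst)
        current = fit(current.design, current.y, new_terms)
    return current, removed
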