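"""Model-adequacy battery: studentized residuals, influence measures,
Box-Cox transformation with shift, and the prediction-precision ratio.

All deletion diagnostics use the standard closed forms in terms of the hat
diagonal, so they agree with brute-force delete-one refitting to numerical
precision while needing only the one fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .basis import TermDescriptor
from .design import Design
from .fitting import FitResult, block_columns, fit

__all__ = [
    "ResidualSet",
    "InfluenceReport",
    "BoxCoxProfile",
    "studentized_residuals",
    "influence",
    "box_cox",
    "apply_transform",
    "inverse_transform",
    "precision_ratio",
    "exclude_and_refit",
]

#: likelihood-ratio cutoff for a ~95% profile CI, chi-square(1) at 0.95 over 2
_LR_CUT = stats.chi2.ppf(0.95, 1) / 2.0

DEFAULT_OUTLIER_T = 3.5


@dataclass
class ResidualSet:
    raw: np.ndarray
    internal: np.ndarray
    external: np.ndarray  # the "outlier-t" statistic; NaN where leverage = 1


@dataclass
class InfluenceReport:
    """Per-run influence diagnostics with the conventional flag thresholds."""

    leverage: np.ndarray
    cooks_d: np.ndarray
    dffits: np.ndarray
    dfbetas: np.ndarray  # (n, p) over the full [terms | blocks] parameter vector
    outlier_t: np.ndarray
    thresholds: dict
    flags: dict  # name -> boolean array per run

    def flagged_runs(self) -> np.ndarray:
        any_flag = np.zeros(len(self.leverage), dtype=bool)
        for v in self.flags.values():
            any_flag |= v.any(axis=1) if v.ndim == 2 else v
        return np.flatnonzero(any_flag)


@dataclass
class BoxCoxProfile:
    shift: float
    lambdas: np.ndarray
    loglik: np.ndarray
    best_lambda: float
    ci: tuple[float, float]
    recommendation: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"lambda": self.lambdas, "loglik": self.loglik})


def studentized_residuals(fitres: FitResult) -> ResidualSet:
    """Internally and externally studentized residuals from one fit."""
    if fitres.df_resid < 2:
        raise ValueError("need residual df >= 2 for externally studentized residuals")
    e = fitres.residuals
    h = fitres.hat
    s2 = fitres.sigma2
    if s2 <= 0:  # perfect fit: all residuals are exact zeros
        z = np.zeros_like(e)
        return ResidualSet(raw=e.copy(), internal=z, external=z.copy())
    one_minus_h = 1.0 - h
    defined = one_minus_h > 1e-12
    internal = np.full_like(e, np.nan)
    internal[defined] = e[defined] / np.sqrt(s2 * one_minus_h[defined])
    # sigma^2 with run i deleted, from the closed form
    s2_i = np.full_like(e, np.nan)
    s2_i[defined] = (fitres.sse - e[defined] ** 2 / one_minus_h[defined]) / (fitres.df_resid - 1)
    external = np.full_like(e, np.nan)
    ok = defined & (s2_i > 0)
    external[ok] = e[ok] / np.sqrt(s2_i[ok] * one_minus_h[ok])
    external[defined & (s2_i <= 0)] = np.inf * np.sign(e[defined & (s2_i <= 0)])
    return ResidualSet(raw=e.copy(), internal=internal, external=external)


def influence(fitres: FitResult, thresholds: dict | None = None) -> InfluenceReport:
    """Cook's distance, DFFITS and DFBETAS with the conventional cutoffs.

    Defaults: Cook's D > 1, |DFFITS| > 2 sqrt(p/n), |DFBETAS| > 2/sqrt(n),
    |outlier-t| > 3.5.
    """
    n, p = fitres.n, fitres.n_params
    rs = studentized_residuals(fitres)
    h = fitres.hat
    one_minus_h = 1.0 - h
    with np.errstate(divide="ignore", invalid="ignore"):
        cooks = rs.internal**2 * h / (p * one_minus_h)
        dffits = rs.external * np.sqrt(h / one_minus_h)
    # DFBETAS_ij = (beta_j - beta_j(i)) / (s_(i) sqrt(G_jj));
    # beta - beta_(i) = G w_i e_i / (1 - h_i)
    G = fitres.cov_unscaled
    Gw = fitres.W @ G  # (n, p): row i = w_i' G
    delta = Gw * (fitres.residuals / one_minus_h)[:, None]
    e = fitres.residuals
    s2_i = (fitres.sse - e**2 / one_minus_h) / (fitres.df_resid - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dfbetas = delta / (np.sqrt(s2_i)[:, None] * np.sqrt(np.diag(G))[None, :])
    th = {
        "cooks_d": 1.0,
        "dffits": 2.0 * np.sqrt(p / n),
        "dfbetas": 2.0 / np.sqrt(n),
        "outlier_t": DEFAULT_OUTLIER_T,
    }
    if thresholds:
        th.update(thresholds)
    flags = {
        "cooks_d": cooks > th["cooks_d"],
        "dffits": np.abs(dffits) > th["dffits"],
        "dfbetas": np.abs(dfbetas) > th["dfbetas"],
        "outlier_t": np.abs(rs.external) > th["outlier_t"],
    }
    return InfluenceReport(
        leverage=h.copy(),
        cooks_d=cooks,
        dffits=dffits,
        dfbetas=dfbetas,
        outlier_t=rs.external,
        thresholds=th,
        flags=flags,
    )


def apply_transform(y, lam: float, shift: float = 0.0):
    """Simple power-family transform: (y + k)^lambda, natural log at lambda = 0."""
    y = np.asarray(y, dtype=float)
    z = y + shift
    if np.any(z <= 0):
        bad = np.flatnonzero(z <= 0)
        raise ValueError(f"y + shift must be positive; offending entries: {bad.tolist()}")
    return np.log(z) if lam == 0 else z**lam


def inverse_transform(t, lam: float, shift: float = 0.0):
    """Inverse of :func:`apply_transform`; round-trips to ~1e-10."""
    t = np.asarray(t, dtype=float)
    return (np.exp(t) if lam == 0 else t ** (1.0 / lam)) - shift


def box_cox(
    design: Design,
    terms: Sequence[TermDescriptor],
    y: Sequence[float],
    shift: float = 0.0,
    lambdas: np.ndarray | None = None,
) -> BoxCoxProfile:
    """Profile log-likelihood of the Box-Cox power family for the model context.

    Uses the scaled transform ((y+k)^lambda - 1)/lambda (log at 0), whose
    Jacobian-corrected profile log-likelihood is
    ``-n/2 log(SSE_lambda / n) + (lambda - 1) sum log(y + k)``.  The ~95% CI is
    the likelihood-ratio region at the chi-square(1) cutoff.
    """
    y = np.asarray(y, dtype=float)
    z0 = y + shift
    if not np.all(z0 > 0):  # also catches NaN
        bad = np.flatnonzero(~(z0 > 0))
        raise ValueError(f"y + shift must be positive for Box-Cox; offending runs: {bad.tolist()}")
    if lambdas is None:
        lambdas = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.01), 10)
    lambdas = np.asarray(lambdas, dtype=float)
    X = design.model_matrix(terms)
    Z = block_columns(design.blocks, design.n_blocks)
    W = np.column_stack([X, Z]) if Z.shape[1] else X
    Q, _ = np.linalg.qr(W)
    logz = np.log(z0)
    n = len(y)
    # transformed responses for every lambda at once: (L, n)
    T = np.empty((len(lambdas), n))
    nz = lambdas != 0
    T[nz] = (z0[None, :] ** lambdas[nz, None] - 1.0) / lambdas[nz, None]
    T[~nz] = logz[None, :]
    proj = T @ Q  # (L, p)
    sse = np.sum(T**2, axis=1) - np.sum(proj**2, axis=1)
    sse = np.maximum(sse, 1e-300)
    loglik = -0.5 * n * np.log(sse / n) + (lambdas - 1.0) * logz.sum()
    best_i = int(np.argmax(loglik))
    inside = loglik >= loglik[best_i] - _LR_CUT
    ci = (float(lambdas[inside].min()), float(lambdas[inside].max()))
    best = float(lambdas[best_i])
    if ci[0] <= 1.0 <= ci[1]:
        rec = "none"
    elif ci[0] <= 0.0 <= ci[1]:
        rec = "log"
    elif ci[0] <= 0.5 <= ci[1]:
        rec = "sqrt"
    elif ci[0] <= -1.0 <= ci[1]:
        rec = "inverse"
    else:
        rec = f"power {best:.2f}"
    return BoxCoxProfile(shift, lambdas, loglik, best, ci, rec)


def precision_ratio(fitres: FitResult) -> float:
    """Signal-to-noise style precision: prediction range over average prediction SD.

    (max yhat - min yhat) / sqrt(p sigma^2 / n) over the design points, with
    yhat the population-average predictions.  Values below 4 indicate the model
    should not be used to navigate the design space.
    """
    yhat = fitres.predict_terms()
    rng = float(yhat.max() - yhat.min())
    if fitres.sigma2 <= 0:
        return np.inf
    avg_var = fitres.n_params * fitres.sigma2 / fitres.n
    return rng / np.sqrt(avg_var)


def exclude_and_refit(fitres: FitResult, runs: Sequence[int]) -> FitResult:
    """Drop the given run indices and refit the same model (outlier-exclusion pathway)."""
    runs = set(int(r) for r in runs)
    keep = [i for i in range(fitres.n) if i not in runs]
    design = fitres.design
    sub = Design(
        [design.points[i] for i in keep], design.space, design.factor, design.n_blocks
    )
    return fit(sub, fitres.y[keep], fitres.terms)
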