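"""File formats, configuration and the end-to-end analysis pipeline.

Design and response tables are plain CSV with an explicit header contract
(one run per row: run_id, block, role, one column per component proportion,
amount_actual, amount_coded, then response columns); the JSON configuration
is the single source of component and response naming.  ``run_pipeline``
chains model-order selection, adequacy checks, optional Box-Cox
transformation, outlier exclusion, backward elimination and reporting for
every response, recording each decision in a structured log.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .adequacy import apply_transform, box_cox, exclude_and_refit, influence, precision_ratio
from .basis import AmountFactor, ComponentSpace
from .design import Design, DesignPoint
from .fitting import anova, backward_eliminate, select_model_order
from .surface import SurfaceModel, slice_grid

__all__ = [
    "config_from_json",
    "space_and_factor_from_config",
    "write_study",
    "read_study",
    "run_pipeline",
]

_META_COLS = ("run_id", "block", "role")
PROPORTION_ATOL = 1e-6


def config_from_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def space_and_factor_from_config(config: dict) -> tuple[ComponentSpace, AmountFactor]:
    space = ComponentSpace(tuple(config["components"]))
    amt = config["amount"]
    factor = AmountFactor(
        amt.get("name", "amount"), float(amt["low"]), float(amt["high"]), amt.get("units", "")
    )
    return space, factor


def write_study(
    design: Design, path, responses: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Write the design (and optional response columns) as one combined CSV."""
    df = design.to_frame()
    if responses is not None:
        if len(responses) != design.n:
            raise ValueError("responses must have one row per run")
        df = pd.concat([df, responses.reset_index(drop=True)], axis=1)
    df.to_csv(path, index=False)
    return df


def read_study(
    path, config: dict
) -> tuple[Design, pd.DataFrame]:
    """Read a combined design+responses CSV against the JSON config contract.

    Component proportion columns must match the configured names exactly and
    row-sum to 1 within 1e-6; any violation is reported with its run id.
    Response columns are whatever remains after the design columns.
    """
    space, factor = space_and_factor_from_config(config)
    df = pd.read_csv(path)
    missing = [c for c in (*_META_COLS, *space.names, "amount_actual") if c not in df.columns]
    if missing:
        raise ValueError(f"design file is missing required columns: {missing}")
    P = df[list(space.names)].to_numpy(dtype=float)
    sums = P.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > PROPORTION_ATOL)
    if bad.size:
        ids = df["run_id"].iloc[bad].tolist()
        raise ValueError(f"proportions do not sum to 1 for run_id(s) {ids}")
    known = set(_META_COLS) | set(space.names) | {"amount_actual", "amount_coded"}
    responses = config.get("responses")
    resp_cols = [c for c in df.columns if c not in known]
    if responses is not None:
        unknown = [c for c in resp_cols if c not in responses]
        if unknown:
            raise ValueError(f"unknown column(s) in study file: {unknown}")
    roles = df["role"].astype(str).tolist()
    blocks = df["block"].to_numpy(dtype=int) - 1
    n_blocks = int(blocks.max()) + 1 if len(blocks) else 1
    points = [
        DesignPoint(tuple(P[i]), float(df["amount_actual"].iloc[i]), int(blocks[i]), roles[i])
        for i in range(len(df))
    ]
    design = Design(points, space, factor, n_blocks)
    design.validate(atol=PROPORTION_ATOL)
    return design, df[resp_cols].copy()


@dataclass
class ResponseReport:
    """Per-response pipeline outcome: chosen model, diagnostics, tables."""

    response: str
    chosen_order: tuple[int, int]
    transform: tuple[float, float] | None
    excluded_runs: list[int]
    removed_terms: list[str]
    anova: pd.DataFrame
    coefficients: pd.DataFrame
    diagnostics: pd.DataFrame
    boxcox: pd.DataFrame
    precision: float
    log: dict
    fit: "object" = None  # the reduced FitResult


def _analyze_response(
    design: Design,
    y: np.ndarray,
    name: str,
    alpha: float,
    alpha_out: float,
    transform: str | dict,
) -> ResponseReport:
    log: dict = {"response": name}
    applied: tuple[float, float] | None = None
    y_work = np.asarray(y, dtype=float)

    sel = select_model_order(design, y_work, alpha=alpha)
    log["order_ladder"] = [asdict(t) for t in sel.orders]
    terms = sel.fit.terms

    # Box-Cox profile on the selected model; shift 1 clears zero values
    shift = 1.0 if np.any(y_work <= 0) else 0.0
    profile = box_cox(design, terms, y_work, shift=shift)
    log["boxcox"] = {
        "shift": shift,
        "best_lambda": profile.best_lambda,
        "ci": profile.ci,
        "recommendation": profile.recommendation,
    }
    if transform == "auto":
        if profile.recommendation != "none":
            lam = 0.0 if profile.recommendation == "log" else round(profile.best_lambda, 2)
            applied = (lam, shift)
    elif isinstance(transform, dict):
        applied = (float(transform["lambda"]), float(transform.get("shift", 0.0)))
    if applied is not None:
        y_work = apply_transform(y_work, *applied)
        sel = select_model_order(design, y_work, alpha=alpha)
        log["order_ladder_transformed"] = [asdict(t) for t in sel.orders]
    log["chosen_order"] = (sel.chosen.mixture_order, sel.chosen.amount_order)
    log["selection_fallback"] = sel.fallback

    fit_full = sel.fit
    rep = influence(fit_full)
    excluded = [int(i) for i in np.flatnonzero(rep.flags["outlier_t"] | rep.flags["cooks_d"])]
    if excluded:
        fit_full = exclude_and_refit(fit_full, excluded)
    log["excluded_runs"] = excluded

    reduced, removed = backward_eliminate(fit_full, alpha_out=alpha_out)
    log["removed_terms"] = [{"term": t, "p": p} for t, p in removed]
    tab = anova(reduced)
    rep2 = influence(reduced)
    prec = precision_ratio(reduced)
    log["r2"] = asdict(tab.r2)
    log["precision_ratio"] = prec
    diag = pd.DataFrame(
        {
            "run": np.arange(1, reduced.n + 1),
            "leverage": rep2.leverage,
            "outlier_t": rep2.outlier_t,
            "cooks_d": rep2.cooks_d,
            "dffits": rep2.dffits,
        }
    )
    return ResponseReport(
        response=name,
        chosen_order=(sel.chosen.mixture_order, sel.chosen.amount_order),
        transform=applied,
        excluded_runs=excluded,
        removed_terms=[t for t, _ in removed],
        anova=tab.to_frame(),
        coefficients=reduced.coef_table(),
        diagnostics=diag,
        boxcox=profile.to_frame(),
        precision=prec,
        log=log,
        fit=reduced,
    )


def run_pipeline(
    design: Design,
    responses: pd.DataFrame,
    out_dir,
    alpha: float = 0.05,
    alpha_out: float = 0.10,
    transform: str | dict = "auto",
    surface_pairs: Sequence[tuple[str, str]] = (),
    resolution: int = 21,
) -> dict[str, ResponseReport]:
    """Run the full analysis chain for every response column and write the bundle.

    Per response: order selection -> Box-Cox (shift 1 applied first when zeros
    are present) -> optional transform + reselection -> outlier exclusion and
    refit -> backward elimination -> ANOVA/coefficients/diagnostics CSVs and
    optional binary-blend surface grids.  A failure in one response's chain is
    logged and the remaining responses continue.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports: dict[str, ResponseReport] = {}
    logs: dict[str, dict] = {}
    for name in responses.columns:
        y = responses[name].to_numpy(dtype=float)
        try:
            rep = _analyze_response(design, y, name, alpha, alpha_out, transform)
        except Exception as exc:  # keep other responses running
            logs[name] = {"response": name, "error": str(exc)}
            continue
        base = out / name
        rep.anova.to_csv(f"{base}_anova.csv", index=False)
        rep.coefficients.to_csv(f"{base}_coefficients.csv", index=False)
        rep.diagnostics.to_csv(f"{base}_diagnostics.csv", index=False)
        rep.boxcox.to_csv(f"{base}_boxcox.csv", index=False)
        model = SurfaceModel.from_fit(rep.fit, response=name)
        for a, b in surface_pairs:
            grid = slice_grid(model, (a, b), resolution=resolution)
            grid.to_frame().to_csv(f"{base}_surface_{a}_{b}.csv", index=False)
        reports[name] = rep
        logs[name] = rep.log
    with open(out / "pipeline_log.json", "w") as fh:
        json.dump(logs, fh, indent=2, default=_json_default)
    return reports


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
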