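"""Synthetic mixture-amount studies shaped like the five-phenolic fly-diet experiment.

The generator emulates a 100-run, five-block study on the simplex of five
phenolic diet additives — (+)-catechin (Ca), phloridzin (Ph), rutin (Ru),
chlorogenic acid (ChA) and p-coumaric acid (pCoA) — crossed with the total
phenolic concentration (75-225 mg per 100 g diet).  Dish-level continuous
responses (weights in mg, development times in days) are true response
surfaces plus Gaussian block and dish noise; percentage responses arise from
binomial sampling of the 30 larvae placed in each dish.

The canonical configuration seeds the true surfaces from published reduced-
model coefficient sets for larval weight, larval and pupal development time
and adult deformity (the latter on its transformed analysis scale), plus four
flat null responses at the untreated-control means.  Everything is driven by
one master seed and regenerates bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import AmountFactor, ComponentSpace, TermDescriptor, amount_range_from_composition
from .design import Design, build_study_design
from .fitting import backward_eliminate, select_model_order
from .surface import SurfaceModel

__all__ = [
    "ResponseTruth",
    "StudyConfig",
    "SimulatedStudy",
    "RecoveryReport",
    "paper_study_config",
    "simulate_continuous",
    "simulate_percentage",
    "simulate_power_response",
    "simulate_study",
    "end_to_end_recovery",
    "COMPONENTS",
    "TABLE_MEAN_CONTENTS",
]

#: canonical component labels (flavonoids then phenolic acids)
COMPONENTS = ("Ca", "Ph", "Ru", "ChA", "pCoA")

#: mean apple-pulp content of each compound, mg per 100 g fresh weight
TABLE_MEAN_CONTENTS = (2.63, 5.87, 0.78, 28.43, 36.79)

#: amount-range multiplier: high = low x 3
AMOUNT_MULTIPLIER = 3.0


@dataclass
class ResponseTruth:
    """True surface and noise model for one response.

    ``kind`` is "continuous" (Gaussian dish noise, optionally on a transformed
    scale given by ``transform = (lambda, shift)``) or "percentage" (binomial
    counts out of ``n_larvae``, truth on the 0-100 scale).
    """

    name: str
    model: SurfaceModel
    kind: str = "continuous"
    sigma_dish: float = 0.0
    sigma_block: float = 0.0
    units: str = ""
    transform: tuple[float, float] | None = None  # (lambda, shift) analysis scale

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "percentage"):
            raise ValueError(f"unknown response kind {self.kind!r}")
        if self.sigma_dish < 0 or self.sigma_block < 0:
            raise ValueError("noise SDs must be non-negative")

    def nonzero_terms(self) -> list[TermDescriptor]:
        return [t for t, c in zip(self.model.terms, self.model.coef) if c != 0.0]


@dataclass
class StudyConfig:
    """Everything needed to regenerate a synthetic study from one seed."""

    space: ComponentSpace
    factor: AmountFactor
    truths: dict[str, ResponseTruth]
    n_model: int = 45
    n_lof: int = 5
    n_replicates: int = 45
    n_centers: int = 5
    n_blocks: int = 5
    n_larvae: int = 30
    seed: int = 0

    def build_design(self, seed: int | None = None) -> Design:
        return build_study_design(
            self.space,
            self.factor,
            n_model=self.n_model,
            n_lof=self.n_lof,
            n_replicates=self.n_replicates,
            n_centers=self.n_centers,
            n_blocks=self.n_blocks,
            seed=self.seed if seed is None else seed,
        )


@dataclass
class SimulatedStudy:
    design: Design
    responses: "object"  # pandas DataFrame, one column per response
    counts: dict[str, np.ndarray]  # binomial counts for percentage responses
    config: StudyConfig
    seed: int


def _truth_model(coefs: dict[tuple[tuple[int, ...], int], float], space, factor, name, units) -> SurfaceModel:
    return SurfaceModel.from_labeled(space, factor, coefs, response=name, units=units)


def paper_study_config(
    sigma_scale: float = 1.0,
    sigma_block_frac: float = 0.5,
    seed: int = 0,
) -> StudyConfig:
    """The canonical five-phenolic study configuration.

    True surfaces for the four affected responses use the published reduced-
    model coefficient estimates (amount on the coded scale); deformity is
    defined on its analysis scale, the shifted power transform (x+1)^-2.6.
    The four unaffected responses are flat surfaces at the untreated-control
    means: pupal weight 21.9 mg, pupation 83.9%, emergence 95.8%, survival
    82.7%.  Dish-noise SDs are scaled by ``sigma_scale``; block-effect SDs are
    ``sigma_block_frac`` times the dish SD.
    """
    space = ComponentSpace(COMPONENTS)
    low, high = amount_range_from_composition(TABLE_MEAN_CONTENTS, AMOUNT_MULTIPLIER)
    factor = AmountFactor("total phenolics", low, high)
    Ca, Ph, Ru, ChA, pCoA = range(5)

    larval_weight = {
        ((Ca,), 0): 21.11,
        ((Ph,), 0): 18.82,
        ((Ru,), 0): 18.71,
        ((ChA,), 0): 21.09,
        ((pCoA,), 0): 19.17,
        ((Ca, ChA), 0): -10.07,
        ((Ca, Ru), 0): 7.97,
        ((Ca,), 1): 1.76,
        ((ChA, pCoA), 0): -12.68,
        ((Ph, Ru), 0): 14.47,
    }
    larval_dev = {
        ((Ca,), 0): 10.60,
        ((Ph,), 0): 10.62,
        ((Ru,), 0): 10.68,
        ((ChA,), 0): 10.79,
        ((pCoA,), 0): 11.07,
        ((Ph, pCoA), 0): -1.83,
        ((pCoA,), 1): 0.23,
    }
    pupal_dev = {
        ((Ca,), 0): 15.06,
        ((Ph,), 0): 15.18,
        ((Ru,), 0): 14.89,
        ((ChA,), 0): 15.01,
        ((pCoA,), 0): 15.25,
        ((Ph,), 1): 0.66,
        ((Ca, ChA), 1): -2.04,
        ((Ca, Ph), 1): -2.32,
        ((Ru, ChA), 1): -1.86,
        ((ChA, pCoA), 1): -1.25,
        ((Ph, Ru), 1): -3.22,
        ((Ph, pCoA), 1): -2.67,
    }
    deformity_t = {  # on the (x+1)^-2.6 analysis scale
        ((Ca,), 0): 0.62,
        ((Ph,), 0): 0.78,
        ((Ru,), 0): 0.75,
        ((ChA,), 0): 0.83,
        ((pCoA,), 0): 0.96,
        ((Ca,), 1): -0.50,
    }

    def flat(value: float) -> dict:
        return {((i,), 0): value for i in range(5)}

    s = sigma_scale
    truths = {
        "larval_weight_mg": ResponseTruth(
            "larval_weight_mg",
            _truth_model(larval_weight, space, factor, "larval weight", "mg"),
            sigma_dish=2.0 * s,
            sigma_block=2.0 * s * sigma_block_frac,
            units="mg",
        ),
        "larval_dev_days": ResponseTruth(
            "larval_dev_days",
            _truth_model(larval_dev, space, factor, "larval development time", "days"),
            sigma_dish=0.27 * s,
            sigma_block=0.27 * s * sigma_block_frac,
            units="days",
        ),
        "pupal_dev_days": ResponseTruth(
            "pupal_dev_days",
            _truth_model(pupal_dev, space, factor, "pupal development time", "days"),
            sigma_dish=0.37 * s,
            sigma_block=0.37 * s * sigma_block_frac,
            units="days",
        ),
        "deformed_pct": ResponseTruth(
            "deformed_pct",
            _truth_model(deformity_t, space, factor, "adults deformed", "%"),
            sigma_dish=0.35 * s,
            sigma_block=0.35 * s * sigma_block_frac,
            units="%",
            transform=(-2.6, 1.0),
        ),
        "pupal_weight_mg": ResponseTruth(
            "pupal_weight_mg",
            _truth_model(flat(21.9), space, factor, "pupal weight", "mg"),
            sigma_dish=1.0 * s,
            sigma_block=1.0 * s * sigma_block_frac,
            units="mg",
        ),
        "pupation_pct": ResponseTruth(
            "pupation_pct",
            _truth_model(flat(83.9), space, factor, "pupation", "%"),
            kind="percentage",
            units="%",
        ),
        "emergence_pct": ResponseTruth(
            "emergence_pct",
            _truth_model(flat(95.8), space, factor, "adult emergence", "%"),
            kind="percentage",
            units="%",
        ),
        "survival_pct": ResponseTruth(
            "survival_pct",
            _truth_model(flat(82.7), space, factor, "neonate-to-adult survival", "%"),
            kind="percentage",
            units="%",
        ),
    }
    return StudyConfig(space=space, factor=factor, truths=truths, seed=seed)


def simulate_continuous(
    design: Design,
    truth: SurfaceModel,
    sigma_dish: float,
    sigma_block: float = 0.0,
    seed: int = 0,
    n_blocks: int | None = None,
) -> np.ndarray:
    """Truth surface + Normal(0, sigma_block) per block + Normal(0, sigma_dish) per dish."""
    if sigma_dish < 0 or sigma_block < 0:
        raise ValueError("noise SDs must be non-negative")
    rng = np.random.default_rng(seed)
    mu = truth.predict(design.proportions, design.amounts)
    b = n_blocks if n_blocks is not None else design.n_blocks
    block_eff = rng.normal(0.0, sigma_block, size=b) if sigma_block > 0 else np.zeros(b)
    dish = rng.normal(0.0, sigma_dish, size=design.n) if sigma_dish > 0 else np.zeros(design.n)
    return mu + block_eff[design.blocks] + dish


def simulate_percentage(
    design: Design,
    truth: SurfaceModel,
    n_larvae: int = 30,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binomial dish counts from a truth surface on the 0-100 scale.

    Truth predictions are clipped to [0.5, 99.5]% before sampling; returns
    (counts, percentages) with percentages = 100 * count / n_larvae.
    """
    if n_larvae <= 0:
        raise ValueError("n_larvae must be positive")
    rng = np.random.default_rng(seed)
    p = np.clip(truth.predict(design.proportions, design.amounts), 0.5, 99.5) / 100.0
    counts = rng.binomial(n_larvae, p)
    return counts, 100.0 * counts / n_larvae


def simulate_power_response(
    design: Design,
    truth: SurfaceModel,
    lam: float,
    sigma: float,
    seed: int = 0,
    y_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Simulate a response that is Gaussian-linear on the Box-Cox(lambda) scale.

    The truth surface is affinely rescaled *on the transformed scale* so that
    the noiseless response spans ``y_range`` on the original scale (the linear
    model holds exactly on the Box-Cox scale, as the transform assumes);
    Gaussian noise with SD ``sigma`` in units of the transformed-scale range is
    added there and inverted back.  Draws outside the transform's domain are
    truncated to it, which at moderate sigma is rare.

    For ``lam < 0`` the transformed scale is bounded above by ``-1/lam``; the
    default ``y_range`` therefore spans 80% of that domain gap (keeping the
    mean well clear of the boundary so truncation stays negligible), and
    (1, 10) otherwise.
    """
    rng = np.random.default_rng(seed)
    mu = truth.predict(design.proportions, design.amounts)
    if y_range is None:
        y_range = (1.0, 0.2 ** (1.0 / lam)) if lam < 0 else (1.0, 10.0)
    lo, hi = y_range

    def fwd(v):
        return np.log(v) if lam == 0 else (v**lam - 1.0) / lam

    zlo, zhi = fwd(np.array(lo)), fwd(np.array(hi))
    z = zlo + (zhi - zlo) * (mu - mu.min()) / (mu.max() - mu.min())
    zr = abs(zhi - zlo)
    zz = z + rng.normal(0.0, sigma * zr, size=len(z))
    if lam != 0:
        # keep 1 + lam*z positive so the inverse stays real
        if lam > 0:
            zz = np.maximum(zz, -1.0 / lam + 1e-9)
        else:
            zz = np.minimum(zz, -1.0 / lam - 1e-9)
        return (1.0 + lam * zz) ** (1.0 / lam)
    return np.exp(zz)


def simulate_study(config: StudyConfig, seed: int | None = None) -> SimulatedStudy:
    """Build the design and simulate every configured response, all from one seed."""
    import pandas as pd

    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    sub = ss.generate_state(1 + len(config.truths)) & 0x7FFFFFFF
    design = config.build_design(seed=int(sub[0]))
    data: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for k, (name, truth) in enumerate(sorted(config.truths.items())):
        s = int(sub[1 + k])
        if truth.kind == "percentage":
            cnt, pct = simulate_percentage(design, truth.model, config.n_larvae, seed=s)
            counts[name] = cnt
            data[name] = pct
        else:
            y = simulate_continuous(
                design, truth.model, truth.sigma_dish, truth.sigma_block, seed=s
            )
            if truth.transform is not None:
                # truth lives on the analysis scale; report on the original scale
                lam, shift = truth.transform
                y = np.clip(y, 1e-6, None)
                y = np.clip(y ** (1.0 / lam) - shift, 0.0, None)
            data[name] = y
    return SimulatedStudy(design, pd.DataFrame(data), counts, config, master)


@dataclass
class RecoveryReport:
    """Aggregated term-recovery and coefficient-coverage rates over replicates."""

    response: str
    n_replicates: int
    term_labels: list[str]
    retention_rate: dict[str, float]  # per true nonzero (non-mandatory) term
    coverage_rate: dict[str, float]  # 95% CI coverage per true nonzero term
    false_inclusion_rate: float  # true-zero terms kept after elimination
    all_retained_rate: float  # replicates retaining every true nonzero term
    all_covered_rate: float  # replicates with every true coefficient inside its CI
    order_chosen: dict[tuple[int, int], int]
    coef_rmse: dict[str, float]


def end_to_end_recovery(
    config: StudyConfig,
    response: str = "larval_weight_mg",
    n_replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    alpha_out: float = 0.10,
    sigma_dish: float | None = None,
    sigma_block: float | None = None,
    design: Design | None = None,
) -> RecoveryReport:
    """Design -> simulate -> select order -> backward-eliminate, replicated.

    The design is built once (it is fixed by the protocol); each replicate
    draws fresh noise, selects the model order by sequential F + lack-of-fit,
    reduces by backward elimination, and records which true nonzero terms were
    retained, whether each true coefficient fell inside its 95% CI, and how
    many true-zero terms survived.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    truth = config.truths[response]
    if truth.kind != "continuous":
        raise ValueError("recovery harness applies to continuous responses")
    sd = truth.sigma_dish if sigma_dish is None else sigma_dish
    sb = truth.sigma_block if sigma_block is None else sigma_block
    if design is None:
        design = config.build_design()
    names = config.space.names
    true_terms = {t: c for t, c in zip(truth.model.terms, truth.model.coef) if c != 0.0}
    watched = [t for t in true_terms if not t.is_linear_mixture]
    labels = {t: t.label(names) for t in true_terms}
    ss = np.random.SeedSequence(seed).generate_state(n_replicates) & 0x7FFFFFFF
    retained = {t: 0 for t in watched}
    covered = {t: 0 for t in true_terms}
    sq_err = {t: [] for t in true_terms}
    order_counts: dict[tuple[int, int], int] = {}
    all_ret = 0
    all_cov = 0
    false_inc = 0
    for r in range(n_replicates):
        y = simulate_continuous(design, truth.model, sd, sb, seed=int(ss[r]))
        sel = select_model_order(design, y, alpha=alpha)
        key = (sel.chosen.mixture_order, sel.chosen.amount_order)
        order_counts[key] = order_counts.get(key, 0) + 1
        reduced, _ = backward_eliminate(sel.fit, alpha_out=alpha_out)
        kept = set(reduced.terms)
        ok_ret = all(t in kept for t in watched)
        all_ret += ok_ret
        for t in watched:
            retained[t] += t in kept
        ci = reduced.confint(0.95)
        term_index = {t: i for i, t in enumerate(reduced.terms)}
        ok_cov = True
        for t, c in true_terms.items():
            if t in term_index:
                i = term_index[t]
                tol = 1e-8 * max(1.0, abs(c))  # zero-width CI at sigma = 0
                hit = ci[i, 0] - tol <= c <= ci[i, 1] + tol
                covered[t] += hit
                ok_cov &= hit
                sq_err[t].append((reduced.coef[i] - c) ** 2)
            else:
                ok_cov = False
        all_cov += ok_cov
        false_inc += sum(1 for t in reduced.terms if t not in true_terms)
    return RecoveryReport(
        response=response,
        n_replicates=n_replicates,
        term_labels=[labels[t] for t in true_terms],
        retention_rate={labels[t]: retained[t] / n_replicates for t in watched},
        coverage_rate={labels[t]: covered[t] / n_replicates for t in true_terms},
        false_inclusion_rate=false_inc / n_replicates,
        all_retained_rate=all_ret / n_replicates,
        all_covered_rate=all_cov / n_replicates,
        order_chosen=order_counts,
        coef_rmse={
            labels[t]: float(np.sqrt(np.mean(v))) if v else float("nan")
            for t, v in sq_err.items()
        },
    )
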