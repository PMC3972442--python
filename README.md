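# mixamount

Mixture–amount experimental design and response-surface analysis for diet and
dose–blend experiments, built around Scheffé mixture polynomials crossed with a
total-amount factor.

## The problem

Feeding studies of plant secondary metabolites (and formulation studies
generally) need to vary two things at once: the *composition* of a blend of
q components — proportions x₁ … x_q with x₁ + … + x_q = 1 — and the *total
amount* (dose) of the blend. Because the proportions are constrained to the
simplex, ordinary factorial polynomials are inappropriate; the canonical bases
are the Scheffé mixture polynomials, which have no intercept and whose linear
("blending") coefficients are the predicted responses of the pure components:

    E[y] = Σᵢ βᵢ xᵢ + Σᵢ<ⱼ βᵢⱼ xᵢxⱼ           (quadratic mixture model)

Crossing each mixture term with powers of the coded amount c ∈ [−1, +1] gives
the mixture-amount model; e.g. the full quadratic × quadratic crossing for
q = 5 has (5 + 10) × 3 = 45 terms. Negative βᵢⱼ means a blend performs below
the linear interpolation of its pure components (antagonistic blending);
positive means synergy.

`mixamount` provides the complete workflow used in such studies, end to end:

* **Design** — candidate-set generation on the simplex × amount space,
  D-optimal point selection by multi-start Fedorov exchange, maximin
  lack-of-fit augmentation, leverage-ranked replication, centroid center
  points, balanced blocking, and the block/model/lack-of-fit/pure-error
  degrees-of-freedom accounting.
* **Fitting** — no-intercept QR least squares with fixed sum-to-zero block
  effects; mixture-convention ANOVA with a joint linear-mixture test, partial
  (Type-III) F per term, and the lack-of-fit / pure-error F test; sequential
  model-order selection; backward elimination with mandatory blending terms.
* **Adequacy** — internally/externally studentized residuals, Cook's distance,
  DFFITS, DFBETAS (all closed-form, matching delete-one refits), Box-Cox
  profile likelihood with shift for zero-laden responses, and the
  prediction-precision (signal-to-noise) ratio.
* **Surfaces** — population-average prediction, binary-blend × amount slice
  grids (the standard contour-figure layout), and simplex-lattice extremum
  search.
* **Synthetic studies** — a seeded generator that emulates a 100-run,
  five-block study of five phenolic diet additives (catechin, phloridzin,
  rutin, chlorogenic acid, p-coumaric acid; 75–225 mg/100 g diet) with
  dish-level Gaussian responses and binomial percentage responses from 30
  larvae per dish, so every pipeline stage is testable without data downloads.

## Worked example

```python
import mixamount as mx
from mixamount.fitting import anova, backward_eliminate, select_model_order

cfg = mx.paper_study_config(seed=42)      # canonical 5-component study
study = mx.simulate_study(cfg, seed=42)   # design + 8 simulated responses
d = study.design

part = mx.df_partition(d, mx.enumerate_terms(5, 2, 2))
# -> 100 runs, 51 distinct points, df = block 4 / model 44 / LOF 6 / pure error 45

y = study.responses["larval_weight_mg"].to_numpy()
sel = select_model_order(d, y)            # sequential F + lack-of-fit gate
red, removed = backward_eliminate(sel.fit)
tab = anova(red)
```

prints (exact output of this script):

```
design: 100 runs, 51 distinct points, df = block 4 / model 44 / LOF 6 / pure error 45
chosen order: quadratic mixture x linear amount = (2, 1)
model p = 3.681e-10, lack-of-fit p = 0.74, R2 = 0.53, R2_adj = 0.47, R2_pred = 0.34
                term  estimate    se      t     p
                  Ca    22.583 0.712 31.739 0.000
        Ca x [Conc.]     2.454 0.672  3.654 0.000
                  Ph    17.787 0.606 29.352 0.000
                  ...
          ChA x pCoA   -17.252 3.585 -4.812 0.000
predicted minimum 14.2 mg at ChA=0.45, pCoA=0.55, 75 mg/100 g
```

Reading the output: the design was selected by sequential F tests as quadratic
mixture × linear amount; the non-significant lack of fit (p = 0.74) says the
residual scatter is replicate noise, not model inadequacy. Blending
coefficients (`Ca` … `pCoA`) are the predicted pure-component larval weights in
mg; the strongly negative `ChA x pCoA` estimate is antagonistic blending — the
chlorogenic/p-coumaric blend depresses larval weight below either pure acid,
and the surface minimum indeed sits near the 50:50 blend of those two acids.

A `mixamount` console script exposes the same stages
(`design`, `simulate`, `fit`, `diagnose`, `surface`, `pipeline`) over CSV/JSON
files; see `mixamount --help`.

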