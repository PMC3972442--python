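# Methods

## Model

The response model is

    y = X β + Z γ + ε,     ε ~ N(0, σ² I)

where `X` is the crossed Scheffé model matrix and `Z` a sum-to-zero coding of
fixed block effects. A term is a mixture part (one component `xᵢ` or a pair
`xᵢxⱼ`) times a power `c^a` (a ∈ {0, 1, 2}) of the coded amount
`c = (amount − mid)/half-range ∈ [−1, +1]`. There is no intercept column: on
the simplex the linear blending terms sum to one, so the intercept is implicit
and one model degree of freedom is absorbed by the blending constraint. All
amount-crossed coefficients are therefore on the coded scale; proportions are
actual proportions (pseudo-component rescaling is not used because the
canonical study lets every component range over the full simplex).

Term order is fixed — mixture parts singles-first then pairs (lexicographic by
component index), amount exponent innermost — so matrices, reports and CSVs
are reproducible bit for bit. Fits use dense QR; there are no iterative
optimizers anywhere in the fitting path.

## Design construction

* **Candidates.** Simplex vertices, binary 50:50 edge midpoints, the overall
  centroid, axial blends (vertex–centroid midpoints) and an optional sparse
  interior lattice, crossed with the coded amount levels {−1, 0, +1}.
* **D-optimal model points.** Fedorov point exchange without replacement:
  at each step apply the single swap maximizing the determinant ratio
  `(1 + d(x_in))(1 − d(x_out)) + d(x_in, x_out)²`, stop when no swap improves
  det(XᵀX) by more than 1e−10 relative, keep the best of ≥10 random starts.
  A small ridge (1e−8 on the normalized scale) keeps early iterations stable
  from singular random starts; the final determinant is checked without it.
  On every instance small enough to enumerate, the exchange result equals the
  exhaustive-search optimum (tested).
* **Lack-of-fit points.** Greedy maximin Euclidean distance in coded space
  (proportions ⊕ coded amount) from the current design — a standard
  distance-based augmentation; the point class is part of the study protocol
  but no selection criterion is prescribed, so maximin was chosen for
  determinism and coverage.
* **Replicates.** The n highest-leverage distinct points under the design
  model are duplicated exactly (ties broken by a seeded shuffle). Replicating
  high-leverage points puts pure-error information where the fit is most
  sensitive.
* **Center points.** n copies of (1/q, …, 1/q) at mid amount. The canonical
  builder withholds the centroid-at-mid-amount candidate from the model and
  lack-of-fit pools (`reserve_centroid=True`): the protocol adds center points
  as their own stage, and reserving the centroid guarantees the distinct-point
  count (and hence the df partition) is identical for every seed.
* **Blocks.** Sizes differ by at most one; runs sharing a distinct point are
  spread across blocks where capacity allows, seeded and reproducible.

### Degrees-of-freedom accounting

With N runs, m distinct points, t terms and b blocks:
block df = b − 1, model df = t − 1, lack-of-fit df = m − t, and pure-error
df = (N − 1) − (b − 1) − (t − 1) − (m − t). The naive replicate count
Σ(nᵢ − 1) overstates pure error because fixed block effects consume replicate
df; the implementation computes pure error as the SSE of the
saturated-in-distinct-points model *with* block effects, whose residual df
equals the partition's remainder. For the canonical design (N = 100, m = 51,
t = 45, b = 5) this gives 4 / 44 / 6 / 45.

## ANOVA and model selection

* **Model row**: reduction in SSE from adding the crossed terms to the
  mean+blocks fit, on t − 1 df, tested against the residual mean square.
* **Linear mixture row**: joint F on the q − 1 equality contrasts among the
  blending coefficients, computed from the full fit's covariance (i.e. after
  block adjustment). Its SS is mathematically bounded by the model SS.
* **Per-term rows**: partial (Type-III) F; for single-column terms this equals
  the squared t statistic.
* **Lack of fit**: F = MS_LOF / MS_PE with (m − t, pure-error) df; flagged
  unavailable when there is no pure error.
* **R² family**: computed against the block-corrected total SS; predicted R²
  uses PRESS from the hat diagonal (identical to brute-force leave-one-out).
* **Order selection** walks the nested ladder linear×linear → quadratic×linear
  → quadratic×quadratic (mixture order raised before amount order, matching
  the model types such studies report), testing each step's added-term block
  with a sequential F and gating on a non-significant lack of fit (α = 0.05).
  The highest qualifying order wins; if none qualifies the lowest order is
  returned flagged.
* **Backward elimination** repeatedly drops the eligible term with the largest
  partial-F p-value above α_out, refitting each round. Linear blending terms
  and block effects are never dropped. α_out defaults to 0.10 rather than the
  testing α of 0.05: published reduced models of this kind retain terms with
  0.05 < p < 0.10, and 0.10 is the conventional stay-threshold. Amount-crossed
  terms are eliminated independently of their mixture parents (no heredity
  enforcement), again matching reported reduced models.

Noiseless data are handled explicitly: an SSE below 1e−18 of the response
scale is treated as an exact fit, under which any real extra SS is infinitely
significant and any zero SS has p = 1, so order selection and elimination
recover the generating term set exactly at σ = 0.

## Adequacy battery

Studentized residuals, Cook's distance, DFFITS and DFBETAS use the standard
hat-diagonal closed forms and agree with delete-one refits to 1e−8 (tested).
Default flags: Cook's D > 1, |DFFITS| > 2√(p/n), |DFBETAS| > 2/√n, and
externally studentized |t| > 3.5 (the conventional outlier-t cutoff; the
diagnostic itself, not the cutoff, is part of the study protocol). The
exclusion pathway drops flagged runs once and refits — no iterative hunting.

Box-Cox uses the scaled transform ((y+k)^λ − 1)/λ (log at λ = 0) with the
Jacobian-corrected profile log-likelihood, a λ grid of [−3, 3] step 0.01, and
a ~95% likelihood-ratio CI (χ²₁ cutoff). The shift k = 1 is applied
automatically when zeros are present. *Applied* transforms use the simple
power family (y+k)^λ, the form in which exponents like (x+1)^−2.6 are quoted;
the two differ only by an affine map at fixed λ, so the chosen λ is identical.
Profile-likelihood CIs show mild finite-sample undercoverage (measured ≈0.91
at nominal 0.95 for n = 100), which the tests account for.

The precision ratio is (max ŷ − min ŷ)/√(p σ̂²/n) over the design points with
population-average ŷ; values below 4 flag a model unfit for navigating the
design space.

## Synthetic studies

The generator emulates the five-phenolic fly-diet study: 45/5/45/5 design
structure, five blocks, dish-level continuous responses and 30-larvae binomial
percentage responses. True surfaces for the four affected responses are the
published reduced-model coefficient sets (coded-amount scale); adult deformity
is generated on its analysis scale, the shifted power (x+1)^−2.6, then
back-transformed and clipped at zero. The four unaffected responses are flat
surfaces at the untreated-control means (21.9 mg pupal weight, 83.9% pupation,
95.8% emergence, 82.7% survival).

Noise defaults are calibrated so the population R² = s²/(s² + σ²) (s = truth
surface SD over the design) matches each response's printed R²: dish σ = 2.0 mg
(larval weight), 0.27 d (larval development), 0.37 d (pupal development), 0.35
(deformity, transformed scale), 1.0 mg (pupal-weight null, consistent with the
control SE of 0.3 at N = 12). Block effects are Normal with σ = σ_dish/2 by
default (no block variance is published; it is explicit configuration, never a
hidden constant). Percentage truths are clipped to [0.5, 99.5]% before
binomial sampling. Everything derives from one master seed via SeedSequence
and regenerates bit-identically.

What the generator does *not* emulate: individual-larva correlation within a
dish beyond the binomial, density dependence, temporal drift within blocks,
non-Gaussian dish noise, and measurement rounding. Passing tests therefore
demonstrate correctness of the design/analysis machinery under the stated
noise model, not robustness to those real-data features.

The Box-Cox recovery generator (`simulate_power_response`) is Gaussian-linear
on the transformed scale with noise at 5% of the transformed range and a
response spanning one decade; for λ < 0 the transformed scale is bounded above
by −1/λ, so the default range spans 80% of that domain gap, keeping boundary
truncation negligible while retaining identifiability.

## Identifiability and known limitations

* With fixed-block estimation and randomly drawn block effects, the surface
  *level* is identified only up to the mean sampled block effect; blending
  coefficients inherit that offset. Parameter-recovery checks therefore
  isolate dish noise.
* Joint recovery of every true term by backward elimination is power-limited:
  at the calibrated noise the weakest true effects sit at |t| ≈ 1.7–2.0, where
  single-term retention probability is ≈0.55–0.65, so some true terms are lost
  in a sizeable fraction of replicates — exactly the regime the original
  study's marginal p-values indicate. The recovery harness reports per-term
  retention, CI coverage, false-inclusion and order-selection rates so this
  is visible rather than hidden.
* Problem sizes in the test suite (e.g. 200-replicate recovery runs,
  1000-replicate null calibration, 200 Box-Cox replicates per λ) were chosen
  as the smallest giving stable binomial bands for the rates being checked.
* Constrained simplex regions, I-/A-optimality, mixed-effect blocks,
  special-cubic mixture terms and GLMs for percentages are out of scope; the
  analysis is ordinary least squares on dish means throughout.
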