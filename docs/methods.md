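# Methods

This note records the models implemented in `granufuse`, the choices made
where the methodology was genuinely open, and what the synthetic studies do
and do not demonstrate.

## Material matching

A formulation material request `(name, grade)` resolves against the
reference database by three rules in strict order:

1. **exact** — normalized `(name, grade)` key lookup (trim, case-fold,
   collapse internal whitespace). The record is returned verbatim.
2. **name-average** — the per-property *equal-weight* mean over all records
   sharing the name. No weighting variable (e.g. market share or batch
   count) is defined for grade families, so equal weights are the only
   defensible default; means are taken over present values (missing entries
   are masked, not imputed).
3. **most-similar** — the nearest database record by Euclidean distance on
   properties autoscaled by the database-wide column standard deviation
   (n−1). The default comparison set is {D₁₀, D₅₀, D₉₀}: particle size is
   the property family on which an uncharacterized active is most defensibly
   matched to an excipient (the canonical case being a micronized active
   matching magnesium stearate). The distance is an RMS over compared
   properties present in both vectors, so partially characterized records
   remain comparable; ties break lexicographically by key so resolution is
   deterministic. The comparison set is user-overridable — the metric is a
   configurable default, not a claim about the uniquely correct similarity.

## Ideal mixing

Mixture property `k` of formulation `i` is `Σ_j w_ij p_jk` — one matrix
product. The linear rule is applied to **all 18 properties**, including
true and tapped density, although densities of blends classically mix
harmonically by mass. This is intentional: the pipeline's unified feature
space is defined by the linear rule, and a harmonic option would silently
change every downstream quantity (ε_min, S′max, model coefficients).
Convexity is the operative invariant: every mixture property lies within
the component-wise extremes.

## Process descriptors

* **Froude number** `Fr = ω² 2R / g`, ω in rev/s (tables carry rpm; the
  conversion is internal). `g` defaults to 9.81 m/s² and is configurable:
  tabulated Fr values in the bundled campaign are internally consistent
  with g between 9.80 and 9.81 only to about 0.2 %, so reconstruction
  checks use a ±0.01 absolute tolerance.
* **Radius.** A measured bowl radius always overrides the geometric
  derivation; absent one, `R = (V/π)^{1/3}` (cylinder with height equal to
  radius). For the 2 L lab bowl the derivation gives 0.0860 m against the
  measured 0.087 m — about 1 % low, which is the error scale to expect for
  literature bowls of unknown geometry.
* **Pore saturation.** `S′max = 100 · w ρ_s (1−ε_min)/(ρ_l ε_min)` with
  `ε_min = 1 − ρ_tapped/ρ_true` of the mixture (tapped density standing in
  for the envelope density of ungranulated powder). The solid density
  `ρ_s` defaults to the mixture **true** density: with generic excipient
  densities this reproduces the 40–110 % saturation magnitudes of real
  campaigns at w ≈ 0.3–1.0, whereas the bulk-density reading yields
  implausible single-digit saturations. Because the literature on this
  descriptor is not unanimous, `density="bulk"` is an explicit switch
  rather than a buried constant. Saturations above 100 % are flagged as
  predicted slurry; flagged candidates are surfaced, never silently
  dropped, because over-wetting is exactly the failure a designed campaign
  should be allowed to probe (and two bundled campaign runs did fail this
  way).
* **Liquid content.** All three reporting forms (volume, mass,
  rate × duration) reduce to the mass ratio w with water density
  1.0 g/mL (configurable). Values outside the 0.025–1.8 g/g span of the
  aligned literature are warned about, not rejected.

## Chemometrics

Single-response NIPALS PLS on autoscaled blocks (n−1 standard deviations;
constant columns are dropped with a warning). For one response the NIPALS
sequence is non-iterative: `w ∝ X'y`, `t = Xw`, `p = X't/t't`,
`c = y't/t't`, rank-one deflation of both blocks. Component signs are fixed
by making the largest-magnitude weight (PCA: loading) entry positive, so
results are independent of row order and reproducible. The pooled
coefficient vector is `B = W(P'W)⁻¹ c`; predictions through `B` and through
the component decomposition agree to numerical precision, and full-depth
PLS on full-rank data equals ordinary least squares (both are test
invariants).

**Q²** uses the cumulative product form `1 − Π_a (PRESS_a / SS_{a−1})`.
`SS_{a−1}` is read as the residual sum of squares *entering* component `a`
on the full-data fit (`SS₀` = total sum of squares about the mean) — the
only reading under which the product telescopes sensibly. `PRESS_a` comes
from refitting the model without each fold and predicting it at depth `a`.
Both are computed in original response units, making each ratio scale-free.
The fold scheme — unstated in most reports — defaults to 7 folds assigned
venetian-blind after one seeded shuffle, mirroring common chemometrics
software; folds and seed are arguments and are recorded with the results.

**Latent-variable count**: smallest depth at which one more component
improves both R² and Q² by less than δ = 0.01 (configurable); the full
per-depth ledger is always returned so the choice can be audited. With
δ = 0 the rule degenerates to the maximum depth, since training R² never
strictly plateaus.

**Hotelling T²** uses `T²_i = Σ_a t_ia²/var(t_a)` with the
`A(N²−1)/(N(N−A)) · F₁₋α(A, N−A)` limit. Outlier screening fits a 2-LV PLS
and excludes at the **formulation** level: a formulation granulating
anomalously (e.g. a pure hydrogel-former forming centimetre aggregates) is
suspect as a whole, so all its runs leave the calibration set together.
Record-level exclusion is available behind a flag. Excluded records keep
their data and carry their exclusion reason.

**Accuracy** counts |error| ≤ deviation with an inclusive boundary; VIP is
`√(K Σ_a SSY_a (w_ak/‖w_a‖)² / Σ_a SSY_a)`, whose squares average to 1.

## Experimental design

One master seed expands into named substreams (L/S, impeller, scale,
selection) via `SeedSequence.spawn`, so adding a stream never perturbs the
others and every draw is independently reproducible. L/S is uniform on its
bounds, impeller speeds are uniform integers (rpm), the bowl scale is
uniform over the configured scales (default 1 L → 0.070 m, 2 L → 0.087 m).
Batch masses per scale are metadata only; no computation consumes them.

## Sieve-based G50

The cumulative undersize mass fraction is interpolated at 0.5 **linearly in
log₁₀(aperture)** — sieve series are geometric, so log-linear interpolation
is the natural choice; linear-in-size is available by argument. An exact
0.5 at an aperture returns that aperture; a crossing outside the stack is
an error that names the violated bound. The default mesh→aperture map
(12→1700, 20→850, 60→250, 80→180, 120→125, 200→75 μm) is configuration,
since national mesh standards differ.

## Synthetic data generator

The generator is the package's fixture factory and defines the study
conditions for the end-to-end checks.

* **Materials.** Two latent factors — size/flow and density/porosity —
  drive the 18 properties, mirroring the two dominant principal components
  real excipient tables show. Derived identities are imposed exactly
  (IH = Dc/Da, IC = 100(Dc−Da)/Dc, porosity = 1 − Da/Dt,
  span = (D₉₀−D₁₀)/D₅₀, ordering of densities and percentiles), so every
  record satisfies the loader invariants by construction. On a 50-material
  draw the first two PCs explain > 60 % of autoscaled variance.
* **Response.** log₁₀ G₅₀ = 2.2 + 0.55·(L/S) + 0.20·(S′max/100) − 0.03·Fr
  − 0.05·span + bias + N(0, 0.05²). The log-linear form keeps G₅₀ positive
  and reproduces the order-of-magnitude spread (roughly 100–2000 μm) of
  real campaigns; liquid content grows granules, shear breaks them, a wide
  inlet size distribution hinders even growth. S′max above 100 % yields a
  slurry failure instead of a size. The PLS stage still models **raw**
  G₅₀, exactly as the pipeline does on real data — the fusion-improvement
  experiment is therefore not rigged in the model's favour by matching
  functional forms.
* **Study structure.** Each literature source emulates one published
  article: a single fixed formulation, one granulator scale (radius derived
  from volume), a narrow L/S window (±0.15 g/g around a source-specific
  center), and a source-specific bias on log₁₀ G₅₀ with standard deviation
  0.1 (≈ 26 % multiplicative) — representing inter-laboratory differences
  in materials, measurement and protocol. Lab runs carry zero bias and
  span the full design space on the 1 L/2 L bowls. All tables are
  materialized in the loader formats and pushed through the real alignment
  code, so the generated datasets have exercised every invariant.
* **Fusion experiment conditions** (chosen once, as the study design): 10
  sources × 14 runs (≈ 140 literature records before slurry failures), 6
  lab runs fused into the calibration set, 30 lab-domain runs (minus
  failures) as the external set, 4 latent variables, 50 seeded replicates.
  The external set is deliberately larger than a real campaign would afford
  so that the Model-1 vs Model-2 RMSEP comparison reflects the systematic
  domain shift rather than small-sample noise.

**What passing does and does not show.** The generator's response is truly
(log-)linear in four features and its material factors are truly
two-dimensional; real granulation is nonlinear (two-regime impeller-speed
effects, hydrogel formers) and real property tables have higher intrinsic
dimension. The synthetic results therefore validate the *machinery* —
alignment, estimation, selection, fusion bookkeeping — and the qualitative
fusion claim under stated bias structure, not predictive performance on any
real formulation.

## Numerical notes and limitations

* Rank exhaustion during NIPALS (vanishing X–y covariance or degenerate
  scores) raises an error rather than returning noise components.
* Hotelling T² treats zero-variance score directions as carrying no
  distance (they contribute 0).
* Materials tables round-trip bit-identically (delimiter sniffing plus
  exact float parsing).
* Problem sizes in the test suite (hundreds of runs, 50 fusion replicates)
  were chosen so the whole suite completes in well under a minute of CPU
  apart from the replicate experiment (~20 s); they are large enough for
  the Monte-Carlo assertions' tolerances, which are stated in the tests.
* The package models G₅₀ only, water as the only binder, and linear PLS
  only (no O-PLS, kernels or multi-response variants). Extrapolation
  beyond the calibration domain is flagged via the T² coverage report, not
  prevented.
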