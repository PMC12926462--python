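# Methods

`isowue` implements an isotope-based reconstruction of intrinsic water-use
efficiency (iWUE) for C₃ and C₄ grasses along an elevation transect, the
mixed-model estimation of its elevational trend, and a machine-learning
attribution of its drivers. Everything is exercisable against a synthetic
transect generator whose ground truth is known, so each stage can be
validated by parameter recovery rather than by eye.

## 1. The physiological chain

### Discrimination

Leaf carbon isotope composition δ¹³C (‰ vs PDB) is converted to
photosynthetic discrimination against ¹³C:

    Δ¹³C = (δ¹³C_air − δ¹³C_leaf) / (1 + δ¹³C_leaf/1000)

δ¹³C of atmospheric CO₂ and the CO₂ mole fraction Ca are boundary
conditions, not measurements; the defaults (−8.5 ‰, 415 ppm, ≈ 2021 global
means) are deliberately conspicuous configuration, echoed into every
output row (`delta13c_air_used`, `ca_used`).

### C₃ formulations

Three nested inversions recover the operative CO₂ concentration from Δ:

* **simple** — Δ = a + (b − a)·Ci/Ca, with a = 4.4 ‰ (diffusion in air)
  and b = 29 ‰ (Rubisco carboxylation). Inversion:
  Ci = Ca(Δ − a)/(b − a).
* **photoresp** (default) — adds the photorespiratory term −f′·Γ*/pCa to
  the forward model, f′ = 12 ‰. Γ* (the CO₂ compensation point without
  dark respiration) is corrected for temperature and pressure:

      Γ*(T, P) = Γ*₂₅ · (P/P₀) · exp(ΔHa (T − 298)/(R·T·298))

  with ΔHa = 37 830 J mol⁻¹, R = 8.314 J mol⁻¹ K⁻¹, and
  Γ*₂₅ = 42.75 µmol mol⁻¹ (a standard literature value; configurable,
  since published transect analyses rarely report the one they used).
  The site's mean annual temperature (converted to kelvin) enters T by
  default; the temperature column is configurable because the choice of
  temperature is a genuine degree of freedom. Pressure follows
  the international-standard-atmosphere barometric profile
  P = P₀(1 − 0.0065·z/288.15)^5.2561 with P₀ = 101 325 Pa.

  *Unit harmonisation.* Γ* is a mole fraction and pCa a partial pressure;
  Γ* is converted to a partial pressure with the same Patm before the
  division, so the correction reduces to f′·Γ*/Ca and is dimensionless
  ‰-scale regardless of elevation.

  *Sign convention.* The inversion consistent with the forward model
  Δ = a + (b − a)Ci/Ca − f′Γ*/pCa **adds** the correction when solving
  for Ci. A variant with the correction subtracted inside the numerator
  circulates in print; `photoresp_sign="printed"` reproduces it. The two
  conventions straddle the simple inversion and differ by
  2·f′·Γ*/(b − a)·Ca/Ca ≈ 10 ppm in Ci at sea level. The
  forward-consistent sign is the default because it is the only one whose
  forward/inverse pair round-trips.

* **mesophyll** — additionally models the drawdown from intercellular
  space (Ci) to chloroplast (Cc) through the conductance ratio
  g_sc/g_m = 0.79:

      Δ = a + (b − a)·Cc/Ca − (g_sc/g_m)(b − a_m)(1 − Cc/Ca) − f′Γ*/pCa

  with a_m = 1.8 ‰ (mesophyll transfer). Inverting gives
  Cc/Ca = 1 − (b − Δ − f′Γ*/pCa)/(b − a + (g_sc/g_m)(b − a_m)). This
  reconstruction was fixed by three contracts — it reduces to the
  photorespiration form as g_sc/g_m → 0, round-trips exactly with its own
  forward model, and yields Cc < Ci (Ci back-derived from the flux
  balance Ci − Cc = (g_sc/g_m)(Ca − Ci)) — the standard way to pin down
  this formulation when published algebra varies. Under this formulation the *operative*
  concentration entering iWUE is Cc; both Ci and Cc are reported.

### C₄ model

    Δ = a + (b₄ + (b₃ − s)·φ − a) · Ci/Ca

with b₃ = 30 ‰ (Rubisco), b₄ = −5.7 ‰ (PEP carboxylation plus preceding
equilibria), s = 1.8 ‰ (bundle-sheath leakage) and leakiness φ = 0.21
(fixed; configurable, since fixed leakiness is a recognised simplification
for field data). At these defaults the slope is **negative** (−4.178 ‰),
so Δ is confined to [0.222, 4.4] ‰ for Ci/Ca ∈ [0, 1] and enriched leaves
imply *high* Ci/Ca. This sign flip relative to C₃ is the mechanism behind
the headline divergence: leaf δ¹³C can rise with elevation in both
pathways while iWUE rises in C₃ and falls in C₄.

Observed C₄ δ¹³C around −13.7 ‰ with δ¹³C_air = −8.5 ‰ gives
Δ ≈ 5.29 ‰, *outside* the model's attainable band — a reminder that the
model-implied range depends strongly on the assumed δ¹³C_air. Such samples
are flagged (`in_range=False`), logged, and never clamped;
`--drop-out-of-range` removes them explicitly.

### iWUE

    iWUE = (Ca − C)/1.6   [µmol CO₂ mol⁻¹ H₂O]

with C the operative concentration (Ci, or Cc for the mesophyll
formulation) and 1.6 the water/CO₂ diffusivity ratio.

f′ (12 ± 4 ‰) and g_sc/g_m (0.79 ± 0.07) carry literature uncertainties;
the central values are defaults and both are plain configuration fields,
so a ± sensitivity sweep is a loop over `FractionationConstants`.

## 2. The synthetic transect generator

The generator emulates the *statistical structure* the analysis assumes,
not the ecology of any particular mountain:

* 98 sites uniform over 40–3800 m (site-placement law unknown; uniform is
  the neutral choice).
* Climate as linear functions of elevation plus Gaussian noise, clipped
  to the observed marginal ranges (MAT 7.6–23.6 °C and VPD 0.2–1.3 kPa
  decreasing, AI 0.4–1.7 increasing, MAP 730–1760 mm decreasing). Noise
  SDs (0.3 °C, 30 mm, 0.04 kPa, 0.05) are small relative to the gradient,
  so the climate block is strongly collinear with elevation — exactly the
  regime the VIF screen exists for, and zeroing the noise makes the
  collinearity exact for screening tests.
* True iWUE per sample: pathway intercept + slope·elevation + species
  random intercept + residual. Defaults: C₃ 35 + 20/km, C₄ 200 − 6/km,
  species SD 12, residual SD 20 µmol mol⁻¹. The C₃ trend reproduces a
  ≈ 2 ‰/km rise in leaf δ¹³C around a mean near −30 ‰; the C₄ trend is
  deliberately weak and kept inside the physically admissible iWUE band
  [0, Ca/1.6] (the C₄ model's validity window). These defaults give a
  marginal R² far below the conditional R² for C₄ (≈ 0.01 vs ≈ 0.23) and
  a strong C₃ trend (≈ 0.38 vs ≈ 0.63) — the qualitative variance
  structure typical of grassland transect surveys, where species
  identity explains much of what elevation alone does not.
* Leaf δ¹³C is then produced by running the *analysis chain in reverse*
  (iWUE → operative C → forward discrimination model at the site's
  pressure and MAT → δ¹³C), so at zero noise the analysis recovers the
  truth to machine precision — the chain identity that anchors all
  recovery tests. Residual draws implying C/Ca outside [0, 1] are redrawn
  (truncated residual) by default, or retained under
  `out_of_range="flag"`.
* One to three dominant species per site, three replicates each (a common
  field-protocol minimum); the probability
  that a slot is C₄ declines logistically with elevation (0.75 ceiling,
  midpoint 1500 m), reflecting C₄ retreat uphill. Species pools default
  to 12 C₃ / 6 C₄.
* δ¹⁸O is phenomenological: a concave quadratic in elevation (peak at
  1800 m, interior to the transect) plus noise. No Péclet/mechanistic
  model is claimed; δ¹⁸O is a carried covariate.
* Stoichiometry: leaf C rises, leaf N and P fall with elevation (so C:P
  and N:P rise — progressive P limitation); soil SOC and soil C:N rise.
  An abundance sheet (6 plots per site, dominants at ~4× cover, a
  background richness pool thinning with elevation) feeds the Shannon,
  richness and CWM covariates.
* All randomness flows from one integer seed through four
  `SeedSequence.spawn` children (sites, species, samples, abundance);
  identical seeds give bit-identical CSVs.

**What passing tests do and do not show.** The generator's noise is
Gaussian, exchangeable within species and site-independent; real leaf
data carry spatial autocorrelation, measurement error in δ¹³C itself,
within-canopy gradients and pathway misclassification, none of which are
modelled. Recovery results therefore validate the *estimators* under the
assumed error structure, not the field inference.

## 3. Community metrics

Shannon–Wiener H = −Σ pᵢ ln pᵢ (natural log; the base is a convention and
is documented rather than assumed), species richness as the mean per-plot
species count, and community-weighted means Σwᵢtᵢ/Σwᵢ with dominance
(pooled abundance) weights by default — biomass weights are an option, since
surveys differ in their weighting basis.

## 4. Mixed models

`iWUE ~ elevation + (1 | species)` fitted by REML (statsmodels `MixedLM`;
cross-checked against lme4 in the test suite). Random intercepts only by
default; random slopes are a configuration away if species are expected
to differ in their elevational response, not just their level.
Variance explained follows the fixed/random decomposition
R²m = σ²_f/(σ²_f+σ²_g+σ²_e), R²c = (σ²_f+σ²_g)/(σ²_f+σ²_g+σ²_e), with
σ²_f the population variance of the fixed-effect linear predictor over
the estimation sample. Fixed-effect p-values are Wald z, and the approximation is recorded in
the fit metadata so downstream reports are explicit about it.
Missing data are removed listwise with the count logged. A fit whose
random-intercept variance collapses to ~0 is returned with a warning and
`singular=True`, never raised, and its R²m ≈ R²c as the formula forces.

Numerical note: statsmodels' L-BFGS path can spuriously converge to zero
group variance on these data; the fit uses the default BFGS optimiser and
falls back to Powell on linear-algebra failures.

## 5. Driver attribution

* **VIF screen.** VIF_j = 1/(1 − R²_j) by per-feature OLS. The single
  highest-VIF feature is dropped and VIFs recomputed until all are below
  10. Exact collinearity (R² = 1 within 1e-12) maps to ∞ and is logged.
  Ties — exact duplicates in particular — are broken by dropping the
  alphabetically last name, which makes the screen independent of column
  order.
* **Boosted trees.** XGBoost regression, depth 3, η = 0.05, 0.8
  row/column subsampling, min_child_weight 5, 200 rounds, fixed seed;
  all hyperparameters are recorded in the output metadata. Early stopping on a seeded 80/20 split is
  available but **off by default**: on weak-signal responses (the C₄
  subset) the validation loss never improves past the first round, early
  stopping returns a one-tree ensemble and its SHAP attributions are
  degenerate. The small fixed budget with shallow, subsampled trees is
  the overfitting control instead.
* **SHAP.** Exact TreeSHAP via XGBoost's `pred_contribs`; per-row
  contributions plus the base value reconstruct the prediction
  (asserted). Importance is the mean |SHAP| per feature; the dependence
  direction is the sign of the Spearman correlation between feature
  values and their SHAP values (a feature the ensemble never splits on
  gets sign 0). Ranking ties fall back to alphabetical order. Models are
  fitted per pathway.

On default synthetic data the recovered directions reproduce the
diverging VPD dependence (negative for C₃, positive for C₄): both arise
from the elevational trends, since VPD falls uphill while C₃ iWUE rises
and C₄ iWUE falls. The attribution stage recovers correlation structure,
not causality — in the generator, climate "drivers" are consequences of
elevation, exactly as along a real transect.

## 6. Problem sizes and tolerances

Round-trip identities are asserted at 1e-9 relative (they hold at ~1e-15;
the slack absorbs platform variation). Recovery checks use 50 transect
replicates for slope coverage and 20 seeds for single-driver attribution;
the default transect (~580 samples) fits and attributes in well under a
second each, so the full suite runs in well under a minute. The
`scripts/acceptance.py` run regenerates everything from scratch at the
given seed.

## 7. Known limitations

* δ¹³C_air, Ca and Γ*₂₅ defaults are assumptions, not data; absolute iWUE
  levels shift with them even though elevational *trends* are robust.
* Fixed C₄ leakiness φ biases absolute C₄ iWUE if φ varies along the
  gradient.
* The mesophyll formulation's algebra is a reconstruction constrained by
  limits and round-trips; its absolute Cc should be treated as
  formulation-specific.
* No spatial autocorrelation, no phylogenetic structure among species, no
  gas-exchange simulation, no mechanistic δ¹⁸O model.
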