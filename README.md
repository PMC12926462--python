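# isowue

Isotope-derived intrinsic water-use efficiency (iWUE) of C₃ and C₄
grasses along elevation transects: the physiological equation chain, the
mixed-model elevational trend, and machine-learning driver attribution —
with a seeded synthetic-transect generator so every stage is testable
against known ground truth.

**Who it is for.** Plant ecophysiologists and stable-isotope ecologists
who have leaf δ¹³C (and optionally δ¹⁸O, stoichiometry, soil and
community covariates) sampled along an environmental gradient and want a
reproducible path from raw per-mil values to "how does water-use
efficiency change along the gradient, and what drives it?"

## The science in brief

Photosynthesis discriminates against ¹³C. For a C₃ leaf,

    Δ¹³C = (δ¹³C_air − δ¹³C_leaf)/(1 + δ¹³C_leaf/1000)
    Δ¹³C ≈ a + (b − a)·Ci/Ca − f′·Γ*/pCa

so measured Δ¹³C can be inverted for the intercellular CO₂ mole fraction
Ci (three formulations: simple, photorespiration-corrected, and a
mesophyll-conductance variant yielding chloroplast Cc). For a C₄ leaf the
bundle-sheath model

    Δ¹³C = a + (b₄ + (b₃ − s)·φ − a)·Ci/Ca

has a *negative* slope at the standard constants (a = 4.4, b = 29,
b₃ = 30, b₄ = −5.7, s = 1.8 ‰; leakiness φ = 0.21), so enriched leaves
mean high Ci/Ca — the opposite of C₃. Either way,

    iWUE = (Ca − Ci)/1.6   [µmol CO₂ mol⁻¹ H₂O]

Γ* is temperature- and pressure-corrected (Arrhenius, ΔHa = 37 830 J mol⁻¹;
barometric pressure from elevation), so the chain is elevation-aware.
Trends are estimated with `iWUE ~ elevation + (1 | species)` (REML) and
summarised by marginal/conditional R²; drivers are screened by VIF < 10,
fitted with XGBoost, and ranked by mean |SHAP| with per-feature dependence
directions. Details, assumptions and design choices: `docs/methods.md`.

## Worked example

The `analysis/` scripts run the full study on a synthetic transect
(98 sites, 40–3800 m) whose true slopes and driver directions are known:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_compute_iwue.py
python analysis/03_fit_trends.py
python analysis/04_attribute_drivers.py --seed 1
```

which prints (abridged):

```
simulated 582 leaf samples at 98 sites (399 C3, 183 C4)
true slopes (per km): C3 +20.0, C4 -6.0
C3: n=399  δ13C mean -28.52 ‰  Δ13C mean 20.62 ‰  Ci/Ca mean 0.681  iWUE mean 82.7 µmol mol⁻¹
C4: n=183  δ13C mean -11.57 ‰  Δ13C mean 3.11 ‰  Ci/Ca mean 0.309  iWUE mean 179.2 µmol mol⁻¹
C3: slope +19.33 [+17.39, +21.26] µmol mol⁻¹ km⁻¹ (truth +20.0), p = 2.4e-85
     R²m = 0.381, R²c = 0.628 (n = 399, 12 species)
C4: slope -3.32 [-7.30, +0.65] µmol mol⁻¹ km⁻¹ (truth -6.0), p = 0.1
     R²m = 0.011, R²c = 0.234 (n = 183, 6 species)
pathways diverge (C3 up, C4 down): yes
C3: VPD dependence sign -1 (generator truth -1) — matches
C4: VPD dependence sign +1 (generator truth +1) — matches
```

Reading it: C₃ leaves are strongly depleted (δ¹³C ≈ −28.5 ‰, large Δ),
C₄ leaves enriched (≈ −11.6 ‰, small Δ). The mixed model recovers the
C₃ trend (+19.3 vs truth +20 per km) with species identity explaining the
gap between marginal (0.38) and conditional (0.63) R²; the C₄ trend is
weak and negative, as generated. VPD associates negatively with C₃ iWUE
but positively with C₄ iWUE — both directions fall out of the elevational
structure, mirroring the diverging field pattern this pipeline is built
to analyse.

The same stages are available as a console tool on any schema-conforming
CSV (`isowue simulate | compute-iwue | fit | attribute | report |
run-all`), e.g.

```bash
isowue compute-iwue --in transect.csv --out iwue.csv --formulation photoresp
isowue fit --in iwue.csv
```

## Layout

    src/isowue/        physio (equation chain), synthetic (generator),
                       community, lmm, attribution, io, pipeline, cli
    analysis/          numbered narrative drivers (simulate → attribute)
    tests/             unit, property and acceptance tests
    scripts/           acceptance.py
    docs/methods.md    model, assumptions, parameters, limitations
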