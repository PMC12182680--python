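# Methods

`forestcarbon` projects the aboveground biomass (AGB) of a gridded forest
landscape decades ahead, combining stand-age growth curves, climate
covariates, CO₂ fertilization, and habitat-suitability-driven changes in
forest extent and composition. This note documents the model, the
defaults, the numerical choices, and what the synthetic world does and
does not emulate.

## The additive biomass model

Per-pixel AGB density (Mg/ha) is decomposed additively:

    C = C_age + C_climate + C_co2

**Age component.** Each forest type carries one saturating growth law
f(t) of stand age t, one of

* Michaelis–Menten (MM): `f(t) = μ·t / (k + t)`, with `k` the age at
  half the asymptote;
* monomolecular (MO): `f(t) = μ·(1 − c·e^{−αt})`, `c ≥ 1`;
* logistic (L): `f(t) = μ / (1 + c·e^{−αt})`, `c ≥ 1`,

each bounded above by the asymptote μ and non-decreasing in t (the `c ≥ 1`
constraint guarantees this for MO and L). A linear climate term extends
the curve to the climate-augmented model

    C^{age+climate}(t, MAT, MAP) = f(t) + a·MAT + b·MAP + d

with MAT in °C and MAP in mm. `C_age` evaluates this expression at the
*future* stand age but the *baseline* (2020) climate; `C_climate` is the
difference made by swapping in the future climate; both may not be
negative biomass, so predictions are floored at zero (see "Numerical
choices"). `C_climate` itself is a difference and may be negative.

**CO₂ component.** Earth-system-model 1pctCO2 experiments supply a
tabulated vegetation-carbon response cVeg(ppm). The fertilization ratio
for a year with concentration `ppm_t` is

    F = cVeg(ppm_t) / cVeg(371.8 ppm)

with 371.8 ppm the 1978–2020 mean baseline concentration, and

    C_co2 = (F − 1) · C_age.

Period ratios (2030s = 2021–2040, 2050s = 2041–2060, 2070s = 2061–2080)
are arithmetic means of the yearly F. When an ensemble of curves is
supplied, F is the mean of per-curve ratios rather than the ratio of mean
cVeg: each model stays self-normalized, so a model with a large absolute
cVeg but the same relative response does not dominate.

## Fitting and model selection

Growth parameters and climate coefficients are estimated jointly per
forest type by bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) from a fixed multi-start grid: μ ∈ {0.5, 1, 2}×max(AGB);
for MM, k ∈ {25, 50, 100, 200, 400, 800} years; for MO/L, c ∈ {1, 10, 10⁵}
and α ∈ {0.01, 0.05, 0.2, 0.8}/yr; climate coefficients start at zero.
The lowest final cost wins, making the fit deterministic for given data.
Bounds enforce μ, k, α > 0 and c ≥ 1.

Families are compared by Gaussian least-squares AIC,
`n·ln(RSS/n) + 2p`, with p counting every free parameter including the
intercept (p = 5 for MM, 6 for MO/L). The best family is the minimum-AIC
fit; exact ties break to the lower RMSE and then to the fixed family
order MM > L > MO. AIC was preferred over raw RMSE/R² because it accounts
for the extra shape parameter of MO/L; RMSE and R² are still reported per
fit.

Under the default study conditions (n = 200 records per type, Gaussian
noise of 10 Mg/ha, ages uniform on [1, 150] years), the recovery study in
the test suite finds median relative errors of ~3% for μ and ~4–6% for
the climate coefficients, and the generating family is selected in
essentially every replicate at noise 5 Mg/ha.

## Map fusion

A pixel is *forest* when fractional tree cover ≥ 20% (inclusive). Three
categorical cover products, ranked by prior reliability, merge
sequentially: (1) a two-product agreement on a **forest** type wins;
(2) otherwise the rank-1 code if it is forest; (3) otherwise the rank-2
code if forest; (4) otherwise the rank-3 code. Note the reading of
criterion (1): agreement on *non-forest* does not short-circuit the
chain — when ranks 1 and 2 both say non-forest, the rank-3 product
decides, which is exactly criterion (4).

Stand age is priority-filled inside the forest mask: the rank-1 product
where non-null, else rank 2, else rank 3 plus its epoch offset (+10 years
for a 2010-vintage global map used at a 2020 baseline). Pixels null in
all three products fall back to the median fused age of same-type pixels
(global median if the type has no donors) and are counted and logged;
the rule is a package choice for a case the priority scheme leaves
undefined.

Inputs must share a grid; a nearest-neighbour regridder is provided for
convenience because it is the only category-preserving resampling.

## Habitat suitability and scenarios

Suitability modelling itself (MaxEnt in the original studies) is external:
the engine consumes, per forest type, a probability surface P ∈ [0, 1]
and an MTSS threshold (maximum training sensitivity plus specificity).
A type qualifies on a pixel iff `P > MTSS` — strictly, reading "exceeds"
literally, so P = MTSS is unsuitable. Collinear environmental variables
are pruned before suitability modelling by greedily dropping the variable
with the most Pearson |r| > 0.8 partners (ties: larger mean |r|, then the
later name drops); Pearson is assumed where the correlation flavour is
unstated.

**Nature scenario** (no disturbance, no planting), per 2020 forest pixel
of type A and age t, N years ahead:

1. remain if P_future(A) > MTSS(A): age t + N, components recomputed;
2. else replace with the most-suitable *other* qualifying type B at age
   N/2 (ties on P break to the lower type code);
3. else the pixel is lost (non-forest, zero components).

Non-forest pixels never gain forest here. N is measured from 2020 to the
period midpoint: 10, 30, 50 years for the 2030s/2050s/2070s (the
evaluation year within a period is otherwise arbitrary; midpoints are
configurable). Each period is projected from the 2020 baseline, not
chained from the previous period, matching the use of 2020 climate inside
`C_age`. N/2 rounds to the nearest whole year by default (Python
banker's rounding; real-valued ages are supported since the curves are
continuous). A replaced or planted stand's CO₂ component uses the new
type's `C_age` — the ratio method is generic in the stand it scales.

**Afforestation scenario.** Policy area targets are near-linear in time;
an OLS line through (year, Mha) points interpolates the period target.
Planting demand is `max(target − nature-scenario remaining area, 0)`.
Candidate pixels are non-forest (in the nature result) with at least one
qualifying type; pixels are drawn uniformly at random without replacement
until the cumulative spherical pixel area meets the demand (so the
planted area overshoots by less than one pixel) or candidates run out,
which is a logged shortfall, not an error. Each planted pixel receives
its most-suitable type at age N/2. The allocation repeats over 10 seeds
and results are averaged; the reported ± on ensemble totals is the
across-replicate standard deviation (ddof = 1), distinct from the spatial
density sd also reported.

Pixel areas are spherical: `R²·Δλ·(sin φ_top − sin φ_bot)` with
R = 6371008.8 m, so Mha accounting is latitude-correct on the lon/lat
lattice.

## Summaries and units

Totals are `Σ density × area × carbon_fraction × 10⁻⁹` in PgC;
sequestration rates `ΔPgC × 1000 / Δyears` in TgC/yr; loss and
structural-change rates are lost/replaced areas over the 2020 forest
area. **carbon_fraction defaults to 1.0**, i.e. input densities are
treated as already in carbon units; the biomass-to-carbon conversion
behind published PgC totals is ambiguous, so the conventional IPCC 0.5
is available but not silently applied. "Average AGB" is the
area-weighted mean density over forested pixels.

## The synthetic world

`synthetic.generate_world` fabricates every pipeline input with known
truth: survey records drawn from per-type growth laws (+ climate term +
Gaussian noise, sd 10 Mg/ha); three cover products perturbed from a true
map at a per-product flip rate solved (by bisection on the closed-form
pairwise-disagreement expression) so any *pair* disagrees at exactly the
configured rate (default 10%); three age products with controlled null
fractions and a −10-year stored offset on the 2010-vintage product;
smooth climate fields (latitudinal MAT gradient, longitudinal MAP
gradient, sinusoidal texture) with constant per-period/SSP deltas of
CMIP6-like magnitude; per-type suitability as a logistic link on the
squared standardized climate distance from type-specific optima, with
MTSS set by quantile so a known fraction of cells (default 40%) qualifies
today; quadratic CO₂ trajectories (≈550 ppm by 2080 moderate, ≈750 ppm
high); a 12-member ensemble of saturating cVeg curves; and a near-linear
area-target series growing 1%/yr with small noise.

Two structural features make the scenario stage meaningful: a *land-use
suppression field* keeps 45% of climatically suitable land unforested
(the candidate pool for planting — the analog of cropland or pasture on
forest-suitable land), and the climate niche breadth is one field
standard deviation, so projected deltas displace habitats without
annihilating them. Generating half-saturation ages (~60–110 yr) sit well
inside the survey age window so asymptotes are identified.

What the generator does **not** emulate: real geography and real
climatologies, spatially correlated survey sampling, classification error
structure of specific cover products (errors are independent flips, not
confusions between similar classes), disturbance history in the age maps,
and suitability surfaces with MaxEnt's feature complexity. Passing tests
therefore demonstrate correctness of the *rules and estimators* under
known truth, not the realism of any national-scale magnitude.

## Problem sizes in the tests

The acceptance suite runs the recovery study at n = 200 × 50 seeds, the
scenario-oracle equivalence on 8×8 worlds × 100 seeds, the conservation
audits on the 50×50 default world, and the end-to-end demo (3 periods ×
2 SSPs × 2 scenarios × 10 replicates) on the 50×50 world — sizes chosen
so the full suite completes in a few minutes on one CPU while every rule
still exercises all branches.

## Known limitations

* Successive periods restart from 2020; compounding succession (a pixel
  replaced in the 2030s then lost in the 2050s) is not represented in the
  default mode.
* The climate term is linear and shared across a type's range; no
  interaction with age.
* F is applied uniformly per scenario (one curve ensemble); per-zone
  curves are supported via source labels but the default world is global.
* Afforestation ignores land-use economics and policy zoning; candidates
  are any suitable non-forest pixel.
* All-null age pixels take a median fill — adequate for rare holes, biased
  if nulls are spatially structured.
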