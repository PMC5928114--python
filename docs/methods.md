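# Methods

This note documents the models, assumptions and numerical choices behind
`fishmerc`, and what the synthetic test scenario does and does not show
about real data.

## Concentration pooling (`fishmerc.hgdb`)

Each literature record is a published mean concentration x̄ᵢ (µg g⁻¹ wet
weight) with sample size nᵢ and optionally a standard deviation sdᵢ. Per
ISSCAAP group the pooled whole-body statistics are

    Hg_w  = Σ nᵢ x̄ᵢ / Σ nᵢ
    SD_w  = √( Σ nᵢ (sdᵢ² + (x̄ᵢ − Hg_w)²) / Σ nᵢ ),   sdᵢ := 0 when absent
    CI_w  = 1.96 · SD_w / √(Σ nᵢ)

SD_w is the pooled-population form: the weighted second moment about the
weighted mean, combining within-study and between-study spread. It is the
estimator we assume for "sample-size-weighted SD"; it makes Hg_w and SD_w
exactly invariant to splitting a study of n observations into two same-mean
sub-studies, which the test suite enforces.

Tissue handling before pooling:

- **fish muscle** → whole body via log₁₀ C_wb = (log₁₀ C_muscle − 0.2545)/1.0623.
  The map is strictly increasing with a fixed point at ≈8.2·10⁻⁵ µg g⁻¹;
  every realistic concentration lies above it, so whole-body values are
  always below muscle values. Non-positive inputs are rejected (log scale).
- **whales** (odontocetes: muscle/bone/viscera; mysticetes:
  muscle/kidney/liver/spleen/lung) → whole body as Σ Cᵢwᵢ with tissue mass
  fractions wᵢ renormalized over the measured tissues, since the measured
  subset does not cover the whole body. Per-tissue records from one
  taxon/source are collapsed into a whole-body pseudo-record whose pooling
  weight is the *minimum* tissue sample size — the most conservative choice,
  since the combined value is no better supported than its weakest tissue.
- **pinnipeds** → direct whole-body burden records, no combination.
- **invertebrates and turtles** → reported concentrations taken as whole
  body.

MeHg-form records never enter THg pools. Whole-body MeHg fractions are 0.58
(fish), 0.46 (invertebrates), 0.39 (turtles) and 0.19 (marine mammals);
edible portions are assigned 0.95. The edible-portion pool uses unconverted
muscle means (whole-body for invertebrates); a group with no edible-eligible
records falls back to its whole-body value with a warning — such groups
(mammals, turtles) have no food-supply counterpart, so the fallback never
reaches the intake calculation. Default trophic levels, habitat flags,
individual-mass equivalences and the ISSCAAP → food-supply-group mapping
ship as one editable fixture (`src/fishmerc/data/group_attributes.csv`).

## Export accounting (`fishmerc.catches`)

Catches in individuals (the three marine-mammal groups) convert to tonnes
with mean individual masses 43 t (baleen whales), 1.29 t (toothed whales)
and 0.231 t (pinnipeds). Export arithmetic is pure unit algebra:
THg [g] = tonnes × Hg_w, MeHg = THg × f_class, kmol = g / (200.59 × 1000)
with the standard atomic weight of mercury. Aggregation is a grouped sum
over any subset of {year, mfa, country, group, tl_bin, zone}; trophic-level
bins round half-up to the nearest integer with bins above 4 merged into 4
(configurable), and the coastal/high-seas zone comes from the per-group
habitat flag (coastal = non-oceanic taxa). Groups lacking concentration data
contribute zero export with a logged warning. Reporting helpers round kmol
to one decimal and shares to integer percent. Ingest excludes inland-water
areas (FAO area codes below 18), plant/coral/sponge/pearl groups, and
aquaculture rows: farmed fish are a net-null mercury budget (mercury
exported at harvest equals mercury imported as feed during growth).

## Trend breaks (`fishmerc.trends`)

`SegmentedModel(endog, exog_years).fit()` estimates
y = β₀ + β₁t + β₂(t − ψ)₊ with exactly one breakpoint per series.
Initialization is a deterministic grid over interior observed years
(preferring years outside 10% margins; always ≥4 points per side); the best
grid RSS seeds the iterative gap-parameter refinement
ψ ← ψ + γ̂/β̂₂, where γ̂ is the coefficient of −1{t>ψ} in the working
linear model. SE(ψ) is the delta-method ratio SE(γ̂)/|β̂₂| — the standard
broken-line estimator, assumed here because no alternative is specified; on
a perfect (noise-free) fit it is legitimately 0. Non-convergence after 50
iterations returns the best grid solution flagged `converged=False`.

`davies_test` bounds the p-value for β₂ = 0, whose breakpoint is not
identified under the null. For candidate breakpoints ψ_k (interior observed
years, ≥4 points per side) it computes the Wald t-statistic s_k of the hinge
term at fixed ψ_k and applies the two-sided small-sample bound

    p = 2·P(T_ν > M) + V·(1 + M²/ν)^(−(ν−1)/2)/√(8π),
    M = max|s_k|,  V = Σ|s_{k+1} − s_k|,  ν = n − 3,

capped at 1; the familiar exponential form is its normal-limit. The t-tail
version matters at yearly-series lengths: simulation (1000 null replicates,
n = 50) puts the empirical size at α = 0.05 near 0.06, within the 0.07
calibration band the test suite enforces, where the normal-tail version is
slightly liberal. Constant series return p = 1 by convention.

Period summaries use the sample SD across years (ddof = 1), defined as 0 for
a single-year period.

## Weekly intake (`fishmerc.exposure`)

WI_j = Σᵢ IR_ij × Cᵢ × 1000 / BM_k / 52 in µg (kg body mass)⁻¹ week⁻¹,
where IR_ij is kg capita⁻¹ yr⁻¹, Cᵢ is the edible-portion MeHg
concentration in µg g⁻¹ (numerically mg kg⁻¹, hence the factor 1000), and
BM_k is the continental mean body mass (Asia 57.7, Africa 60.7, Latin
America & Caribbean 67.9, Europe 70.8, Oceania 74.1, North America
80.7 kg). Cᵢ is built per food-supply group as 0.95 × the sample-size-
weighted mean of member groups' edible-portion THg; the table is injectable
so a directly measured MeHg table can replace the factor-based one. WI is a
*potential* intake: supply (availability after trade, non-food uses and
waste), not measured consumption. Decade averages are across-years mean ±
SD per country; countries enter a period only from their first year of
data. Exceedance summaries count countries with period-mean WI above the
PTWI (default 1.6 µg kg⁻¹ week⁻¹), report integer percentages, stratify
exceeders by SIDS/LDC status, and rank by descending WI; "N times the PTWI"
is the floor of the ratio. Countries with zero marine supply get WI = 0 and
count as non-exceeding.

## Synthetic scenario (`fishmerc.synth`)

The generator emulates the three input streams, not any real statistical
series:

- **Catches** (1950–2014, five Major Fishing Areas, fourteen groups):
  piecewise-linear trends plus Gaussian noise truncated at zero. Oceanic
  groups accelerate after a 1975 breakpoint (high-seas expansion), coastal
  groups rise to 1989 then decline slightly, whaling declines throughout;
  2014-scale levels are realistic magnitudes (e.g. ~7.5 Mt tunas-like,
  ~15 Mt herrings-like). Mammal groups are emitted as whole individuals
  (floored), so their tonnages are multiples of the mass equivalences.
- **Concentration records**: per group, study means log-normal about the
  configured median (default natural-log SD 0.4 — about ±50% study-to-study
  spread, typical of literature compilations) with sample sizes uniform on
  5–200. Fish records are emitted as *muscle* concentrations via the inverse
  allometric map so that pooling must exercise the conversion; medians are
  anchored to published whole-body levels for the extremes (tunas-like 0.38,
  oysters-like 0.015 µg g⁻¹, a 25× trophic contrast). Two MeHg-form records
  are included to exercise their exclusion.
- **Supply** (1961–2011, ten fictional countries): profiles span zero
  (landlocked), low (~0.3), near-threshold (a world-average-like profile
  whose expected WI equals the PTWI by construction: Σ IR·E[C] with
  E[C] = median·e^{σ²/2}·0.95), moderate, and extreme (a pelagic-dominated
  island at ~160 kg capita⁻¹ yr⁻¹, WI > 20). One country starts reporting
  in 1988 to exercise absent early periods. Noise is multiplicative
  log-normal (log-SD 0.08).

All randomness flows from one seed through named child streams, so runs are
bit-reproducible and the three tables are independently reproducible.
Setting every noise scale to zero (`noiseless_config`) makes the full
pipeline analytically invertible: `ground_truth` evaluates the configured
trends and medians in closed form, an independent route the end-to-end test
matches at 10⁻⁹ relative tolerance.

What passing these tests shows: the accounting arithmetic, conversions,
pooling, aggregation identities and estimator calibration are correct.
What they do not show: anything about real FAO series (no under-reporting,
no trade network, no species-level resolution, no temporal decline in
concentrations — the latter deliberately not modelled, matching the
uncorrected accounting convention).

## Problem sizes and runtime

Default test-suite problem sizes are chosen to keep the statistical checks
meaningful at interactive runtimes: 65-point yearly series; 500 replicates
for breakpoint-recovery moments and 200 for ±2·SE coverage; 1000 null
replicates for Davies-test size; 100-record pooling oracles; 50-country
intake oracles; 10,000-record law-of-large-numbers pooling check. The whole
suite runs in well under a minute on one CPU.

## Known limitations

- Breakpoint SEs from the delta method are mildly anti-conservative at low
  signal-to-noise (empirical SD of ψ̂ exceeds the mean reported SE by
  ~10–25% in simulation); coverage of ±2·SE intervals is ≥90% only once
  |Δslope|/σ ≳ 5.
- One breakpoint per series is imposed, and inference ignores serial
  correlation in the annual series.
- The SD_w/CI_w estimator and the whale pseudo-record weight are assumed
  forms (stated above), not uniquely determined by the quantities they
  summarize.
- Exposure SDs are across-years only; concentration uncertainty (SD_w) is
  reported but not propagated into WI.
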