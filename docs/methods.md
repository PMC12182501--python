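# Methods

## Respiration models

Soil respiration is treated as two independent fluxes summed: heterotrophic
respiration (HR) from microbial decomposition of soil organic carbon, and
soil autotrophic respiration (AR) from fine roots. Both are evaluated
pointwise from driver states — no soil carbon pool dynamics, no lags.

**HR.** Three candidate structures share an exponential temperature factor
e^(βT) scaled by SOC. HR₁ adds a linear moisture modifier (α + γM); HR₂ a
Michaelis–Menten moisture saturation M/(M + k_M); HR₃ a Liebig-style
minimum of temperature and moisture saturation terms,
min(T/(T + k_T), M/(M + k_M)). In HR₃ temperature enters twice (through the
saturation term and the exponential); the form is implemented as stated,
since the double appearance is what lets the model damp mid-summer fluxes
when moisture is limiting. The temperature saturation term is clamped to
[0, 1]: field sites stay above freezing, but synthetic forcing may dip
below 0 °C and an unclamped term would flip the sign of the flux.

Units are fixed package-wide: fluxes g C m⁻² day⁻¹, T in °C, M as
volumetric percent (0–100). α absorbs the SOC (g kg⁻¹) to flux conversion;
γ and k_M take percent-moisture units.

**Half-saturation rule.** k_T and k_M are set to half the record maximum of
the corresponding driver over the calibration record (the record maximum,
not a climatological one — the literal reading of the convention). The rule
is undefined when the record maximum temperature is non-positive.

**AR.** Maintenance respiration Rm = FRB·δ·ε^((T−20)/10) with fine-root
biomass FRB = P_rl·LAI/SLA; growth respiration Rg = 0.25·P_rt·NPP with
NPP = GPP − AR/P_rt. Because AR appears on both sides, the system is linear
in AR and reduces to AR = (1/1.25)·Rm + (0.25/1.25)·P_rt·GPP = 0.8·Rm +
0.03·GPP at the default P_rt = 0.15. The 0.8 and 0.03 coefficients are
always derived from the growth fraction and P_rt, never hard-coded, so
non-default allocations stay self-consistent. `ar_system_solve` solves the
system by damped fixed-point iteration (contraction factor 0.25, tolerance
1e−14) precisely so that the numeric route is independent of the closed
form and the two can cross-validate.

δ carries units g C (kg C fine root)⁻¹ day⁻¹ so that Rm lands directly in
g C m⁻² day⁻¹; FRB is exported in g C m⁻² (×1000) only for display. The
shipped defaults δ = 2, ε = 2 are placeholders documented as such: site
work must supply biome look-up-table values or fit them.

Biome constants: P_rl = 1.1 (evergreen broadleaf) / 1.2 (evergreen
needleleaf); SLA = 25.9 / 14.1 m² per kg C; P_rt = 0.15; growth fraction
0.25. All are configuration, overridable per site.

## Calibration

Plain unweighted least squares (Gaussian additive residuals, no weighting),
minimised with scipy's bounded trust-region-reflective solver. Free
parameters: (α, γ, β) for HR₁, (α, β) for HR₂/HR₃ with k_T, k_M fixed by
the half-of-maximum rule beforehand. Bounds: α ≥ 0, γ ≥ 0, β ∈ [0, 0.2];
for AR, δ ≥ 0, ε ∈ [1, 4]. Initialisation is deterministic and
data-driven: α₀ from the mean observed flux over SOC times the mean
dimensionless model factor, β₀ ∈ {0.02, 0.05, 0.08}, plus two α scalings
(×0.3, ×3) at the central β — five starts, best residual sum of squares
kept. Non-convergence from every start is flagged on the result rather than
raised. The parameter covariance is the Gauss–Newton estimate s²(JᵀJ)⁻¹.

The AR "BPLUT" path performs no optimisation: it echoes the fixed biome
constants, reports k = 0 and the diagnostic RSS against the observations.

## Model selection

Origin-R² is the standard uncentred R² (1 − Σ(y − bx)²/Σy², b = Σxy/Σx²),
with an F test on (1, n−1) degrees of freedom; the seasonality slope is the
ordinary intercept-included regression of observed on modelled rates.
AIC = 2k + n·ln(RSS/n) with RSS the direct model–observation residual sum
of squares; a perfect fit (RSS = 0) maps to −∞ with a warning. Ranking is
mean AIC across sites, tie-broken by mean RMSE, then mean |slope − 1|; the
slope and NSD columns are carried in the comparison table because a model
can be preferred on seasonality despite a slightly worse AIC.

## Temporal statistics

Seasons are fixed meteorological MAM/JJA/SON/DJF; DJF winters are labelled
by the January year. Seasonal amplitude and C.V. are computed on the 12
calendar-month climatological means (C.V. = 100·sd/mean). Trends are OLS on
the year index with a two-sided t test. DSD is the sample standard
deviation (n−1) of residuals after removing the OLS line; NCV = 100·DSD /
mean of the original series — the literal reading of "normalized C.V.". The
summer-vs-winter contrast of the HR/SR and AR/SR fractions uses a paired
(by year) two-sided t test.

## Attribution and ENSO composites

First-order attribution evaluates the partial derivatives at the
reference-year driver state and forms term_i(year) = ∂f/∂x_i ·
(x_i(year) − x_i(ref)). Central finite differences (relative step 1e−6 per
coordinate) are the default derivative route for HR₃ because the min() is
non-smooth; analytic partials use the active branch, taking the moisture
branch at an exact tie by convention. Relative contributions are
100·mean|term_i| / Σ_j mean|term_j| across years — a mean-absolute
convention chosen because a single percentage per driver is wanted even
when terms change sign across years; an endpoint-based alternative is
exposed as an option. The first-order residual (actual change minus the sum
of terms) is reported per year; for the smooth models it shrinks
quadratically with perturbation size.

ENSO winters are classified by the DJF-mean ONI with the conventional
±0.5 °C thresholds (configurable); winters with fewer than two of the three
DJF months are omitted. Composites are computed on the linearly detrended
winter series with the grand mean added back. Note that the "relative
change vs the all-year detrended mean" of an inflated class is diluted by
the inflated years' presence in that mean; the class anomaly (composite
minus grand mean) and the change vs the neutral-class composite are the
undiluted measures, and the anomaly is the quantity exactly invariant to
linear trends in the input.

Driver–response correlations are plain Pearson r with two-sided p and no
multiplicity correction; the output table records that explicitly.

## Synthetic generator

Each driver is mean + sinusoid (peak near mid-July) + a yearly AR(1)
anomaly (sd 3 % of the driver mean, lag-1 coefficient 0.4) + 1 % daily
white noise. Soil moisture is clipped to [5, 60] %, LAI floored at 0.3, GPP
at 0. GPP co-varies with the LAI and temperature deviations from their
seasonal cycles through a linear link (1.0 g C m⁻² day⁻¹ per unit LAI,
0.1 per °C). Winter soil temperature carries an ENSO-coupled anomaly of
0.5 °C per °C of DJF-mean ONI; the synthetic ONI is a 3-month running mean
of a monthly AR(1) process (φ = 0.9, sd 0.7 °C). Observations are biweekly
subsamples with multiplicative N(0, 10 %) noise truncated at zero (chamber
flux errors scale with magnitude; the truncation bias is negligible at the
default noise level); SR observations are formed as HR + AR after noising,
so HR ≤ SR holds by construction.

Three archetypes carry the site constants: SOC 30.9 / 22.7 / 8.4 g kg⁻¹
and seasonal soil-temperature ranges 18.1 / 15.3 / 20 °C for the broadleaf
and the two needleleaf sites, with HR₃ truth parameters α = 0.07 / 0.03 /
0.11 and β = 0.0236 / 0.0594 / 0.039 respectively. Annual-mean soil
temperatures (17 / 14 / 18 °C) and the moisture climatology (30 ± 8 %) are
set to subtropical-realistic values; the moisture mean sits near the HR₃
half-saturation point so that moisture limitation is genuinely active. The
greening scenario used in the validation suite applies an LAI trend of
0.04 yr⁻¹ (≈ 0.4 per decade), consistent with the strong vegetation
greening observed in southern-China planted and secondary forests over the
2000s–2010s, at the needleleaf archetype whose low SLA makes root biomass
the first-order AR driver.

What the generator does *not* emulate: trenching artifacts (root-decay CO₂
pulses after plot installation), within-site spatial heterogeneity,
rainfall pulse responses (Birch effects), droughts breaking the sinusoidal
moisture climatology, or satellite retrieval noise structure. Passing the
recovery and selection tests therefore demonstrates the statistical
machinery is correct under the assumed data-generating process, not that
the models are adequate for any particular field site.

## Problem sizes and numerical choices

The validation suite uses 3-year calibration records (≈ 79 biweekly
observations), 200 Monte-Carlo replicates for parameter recovery, 100 for
model selection, and 21-year simulations for trend/attribution/ENSO
checks — sizes chosen to give stable Monte-Carlo rates while keeping a full
run around a minute. Derivative cross-checks exclude HR₃ states within
1e−3 of the min-branch switch, where a symmetric difference straddles the
kink and no single derivative exists. Fixed-point iteration for the AR
system stops at 1e−14 absolute; interpolation of drivers to observation
dates is linear with extrapolation forbidden.

## Known limitations

HR has no microbial biomass, community composition, or substrate depletion
terms; AR has no mycorrhizal or rhizosphere compartments and its
parameters do not vary under climate extremes. Attribution is first-order
only and evaluated at the reference-year state, so large driver excursions
leave a visible residual. The ENSO analysis is contemporaneous-winter
compositing; no lagged teleconnections.
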