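# Methods

This note documents the model equations as implemented, the numerical
choices, the synthetic-data generator, the calibration machinery and
the known limitations. Units are SI internally (Pa, K, s, mol, m)
except where a quantity is conventionally carried otherwise (MPa and mm
in the stem module, hours in the growth module); I/O uses the field's
customary units (°C, µmol m⁻² s⁻¹ PPFD, mm rain per step, cm
water-table depth, µm dendrometer readings).

## Gas exchange

Stomatal conductance for CO₂ maximises the instantaneous net gain
`A(g) − λ·1.6 g D`. Under the supply–demand assimilation model

    A(g) = g (f C_a − R) / (g + f),

obtained by eliminating the internal CO₂ concentration from supply
`g (C_a − C_i)` and linear demand `f C_i − R`, the stationarity
condition `dA/dg = 1.6 λ D` has the closed-form root

    g* = f [ √((C_a − R/f)/(1.6 λ D)) − 1 ],

and the applied conductance is `g_σ = max(g0, g*)`: darkness (`f = 0`),
respiration exceeding gross supply, or high evaporative demand all
collapse to the minimum-conductance floor `g0`. The light response
`f = ι γ I /(ι I + γ)` uses `ι = max{c (S − S0), 0}` in m³ mol⁻¹, so
PPFD is converted from µmol to mol m⁻² s⁻¹ inside the product `ι I`
(the only reading under which the printed units of `c` and `γ` are
dimensionally consistent). The acclimation state S follows
`Ṡ = (T_l − S)/τ_S` with `τ_S = 12 d` and leaf temperature
`T_l = T + I/1500` (a linear radiative-load correction; the slope is a
configurable constant). Respiration is `R = R0 Q10^(T_l/10)`.
Net assimilation is reported with the −R term; a gross form (no
respiration) is available via `include_respiration=False`.

Hydraulics enter through `log10 λ = z0 + z1 log10(k_sl/k0)` with
`z0, z1 < 0`: a well-watered pathway (large `k_sl`) means cheap water
and small λ. Conductances along the chain are carried as dimensionless
multiples of the reference `k0 = 2.22×10⁻⁸ mol m⁻² leaf s⁻¹ Pa⁻¹`, so
the ratio in the λ correlation is O(1). The soil-to-root leg is
`k_sr = ξ_m (θ/θ_sat)^{ξ_p}` on mineral soil. On peat it is unimodal in
water-table depth σ: the waterlogging branch
`k_sr⁻ = η_m((2θ* − θ)/θ_sat)^{η_p}` applies on the wet flank
(σ < σ* − 15 cm), the drying branch `k_sr⁺` on the dry flank
(σ > σ* + 15 cm), and the 30-cm band between them is a plateau at the
mean of the two branch maxima (evaluated at the plateau edges). The
orientation follows the physics — waterlogging harms uptake when the
water table is shallow — and makes the curve unimodal with its optimum
at σ*; if waterlogging is total (`2θ* ≤ θ`) a small positive floor
(10⁻⁹ k0) keeps downstream harmonic sums defined. The root-to-leaf leg
is anchored to data: `k_rl = max_t J(t)/(ρ Δψ_sl_max)`, the seasonal
sap-flow maximum over the species' maximum soil-to-leaf potential
difference (3 MPa for peatland spruce, 2 MPa for mineral-soil pine).

## Soil water

Peat: volumetric water content from water-table depth via the Van
Genuchten form `θ(σ) = θ_res + (θ_sat − θ_res)[1 + (0.072σ)^{1.371}]^{1/1.371 − 1}`
(coefficients taken as given for Finnish drained peat), and water
potential `ψ = −[S_e^{−4.4248} − 1]^{0.0231/0.774} cm × 98.2 Pa cm⁻¹`
on effective saturation `S_e`. The exponent grouping is the one that
satisfies `ψ(θ_sat) = 0` and monotonicity; it lives in a single
function so alternative readings can be swapped. Mineral soil:
Campbell retention `ψ = ψ_e (θ/θ_sat)^{(3 − ξ_p)/2}` with air entry
`ψ_e = −745 Pa`; the exponent follows from the Campbell relation
between the conductivity power `ξ_p = 2b + 3` and the retention power
−b. θ_res is not published for either site; the package defaults to
0.10 (peat) and 0.03 (mineral) m³ m⁻³ as documented placeholders.
Mineral-soil SWC is smoothed with a trailing 24-h moving average before
use.

## Stem water and the elastic component

The bark is a linear capacitor: `q̇_b = J_bin − k_bc E_b q_b / d_b0`,
with influx `J_bin = min(α_rain w_rain/Δt, J_bin_max)` during rain. The
influx slope α_rain is unpublished; the default saturates the clamp at
1 mm h⁻¹ of rain and is exposed in configuration. Cambial water
potential is assembled algebraically each step,

    ψ_cam = ψ_s − J/(ρ k_sb) + (E_b/d_b0) q_b − Δψ_g,

with `Δψ_g = 0.01473 MPa` (ρ_w g l_rb for l_rb = 1.5 m) and the
soil-to-breast-height conductance `1/k_sb = 1/k_sr + 1/k_rb`,
`k_rb = k_rl (height + l_rb)/l_rb` (conductance scales inversely with
path length). Constant osmolality makes turgor dynamics equal ψ_cam
dynamics, so the reversible SRD component is the exact differential
`Δd_ela = Δψ_cam · d0/E` — it sums to zero over any closed ψ_cam loop.
The stem modulus E is linear and constant per tree-year. In calibration
mode the drawdown uses the observed sap flow (missing values carried
forward); in closed-loop mode it uses modelled transpiration delayed by
the height lag β·height (β in min m⁻¹, rounded to whole 30-min steps).

## Cambial growth

Extensibility (MPa⁻¹ h⁻¹):

    φ(T) = φ_max · a T e^{ΔH_A/(RT)} / (1 + e^{ΔS_D/R − ΔH_D/(RT)}),  T ≥ T_0,

zero below the temperature threshold `T_0` (air temperature in kelvin;
`a = 5.3544×10¹² K⁻¹`, `R = 8.3145 J mol⁻¹ K⁻¹`). With `ΔH_A < 0` the
numerator rises Arrhenius-like; the denominator switches on
deactivation near `T = ΔH_D/ΔS_D`, making φ unimodal. The Lockhart
rate is `p = φ(T)(ψ_cam − ψ_0)` above the turgor threshold `ψ_0`, so
growth requires jointly `T ≥ T_0` and `ψ_cam ≥ ψ_0`. The phenology
envelope is the Gompertz derivative

    N_c(t) = N_c^max (b T_u/τ_G) exp(−b e^{−t/τ_G} − t/τ_G),  T_u = 1 h,

clocked in hours from 00:00 of the seasonal start day (DOY 132,
configurable); it peaks at `t* = τ_G ln b` and integrates to
`N_c^max T_u (1 − e^{−b})` cell-hours. The growth rate is
`ḋ_gro = g_f N_c p d̄_c / ln 2`: cells double their volume before
dividing, so with isotropic linear expansion the division rate is
`3p/ln 2`; the geometry factor `g_f ∈ {3, 1}` is a configuration
switch (default 3) because the factor is absorbed by φ_max during
calibration. AM1 replaces `N_c` by the constant ceiling
`N_c^max = 8.85`; AM2 replaces `p` by `φ_max × 1 MPa`. Both variants
keep g_f so the three modes differ only in the frozen factor.

With mid-prior parameters on stationary drivers the three variants
produce the expected contrast: FM daily increments rise and then fall
(sigmoid cumulative curve), AM1 is exactly linear, and AM2 reproduces
the pure Gompertz antiderivative.

## Numerics

All state advances on the 30-min driver grid with forcing held constant
within a step. The two linear capacitor states (S and q_b) use the
exact exponential update for piecewise-constant forcing — for the bark
store the time constant `d_b0/(E_b k_bc)` is only ~5 h, where a plain
first-order update would leave visible discretisation error — and the
growth integral uses a rectangle rule at the step start. A reference
integrator (RK4 at dt/100 inside each driver step) bounds the scheme's
error: over a full 153-day season S, q_b and ψ_cam agree to machine/
quadrature precision and the stem radial dimension to ~10⁻⁴ relative
RMSE (normalised by the reference signal's variability), well inside
the 1% band asserted in the tests. Degenerate inputs resolve
conservatively: VPD is floored at 10⁻⁹ mol m⁻³ in the conductance
optimum, non-real or sub-floor optima fall to g0, and negative
radicands mean the floor. Growth increments are exactly non-negative by
construction, so cumulative growth is monotone.

## Synthetic data

The generator emulates a southern-Finland site-year at 30-min
resolution: temperature as seasonal (annual mean 4 °C, amplitude 12 °C,
peak at DOY 196) plus diurnal (amplitude 4 °C, warmest at 15:00)
sinusoids with AR(1) weather noise (SD 1.5 °C, lag-1 coefficient 0.95);
PPFD as a daylight half-sinusoid (clear-sky peak 1500 µmol m⁻² s⁻¹,
day length following ~61.5° N) scaled by a daily cloudiness factor that
is lower on rain days; VPD from the Magnus saturation curve at relative
humidity 0.70 (0.96 during rain); rain as Poisson events (0.3 day⁻¹,
exponential depths of mean 5 mm, geometric durations of mean 3 h); and
a one-bucket soil store — water-table depth deepening under radiation
and recharged by rain on peat (clamped to the observed 4–75 cm range),
volumetric water content on mineral soil (clamped to
[θ_res + 0.02, θ_sat]). An optional drought window suppresses rain.
Every draw derives from one seed; the full pipeline is bit-reproducible.

Observations are closed-loop: the model runs at "true" parameters
(prior-box midpoints; Table-type constants for the peat/spruce site by
default), sap flow is `ρ E` delayed by the β·height lag plus iid
Gaussian noise (SD 0.5 mol m⁻² sapwood s⁻¹), and the dendrometer series
is the modelled SRD plus noise (SD 20 µm). Two self-consistency choices
matter for parameter recovery. First, the closed-loop root-to-leaf
conductance is the fixed point of the same sap-flow-maximum anchoring
the calibration applies, so both sides of the inference agree on the
hydraulic normalisation. Second, the dendrometer truth is re-simulated
in calibration mode conditioned on the noisy sap-flow record, making
the generative process identical to the statistical model the
likelihood assumes — the configured noise SDs are then the only
model–data mismatch, which is what a recovery experiment should test.

What the generator does not emulate: instrument drift and discrete
sensor failures, the covariance structure of real weather (fronts,
persistent synoptic regimes), snowmelt and freeze–thaw events outside
the growing season, and between-tree competition. Passing tests
therefore demonstrate internal consistency and estimator correctness,
not field validity. A further property of the chosen study conditions:
with prior-midpoint hydraulic parameters the midday soil-to-stem
drawdown is deeper than field-typical values, so the synthetic tree
shows exaggerated diurnal shrinkage and accumulates most of its growth
at night — qualitatively the right behaviour, quantitatively at the
harsh end. Calibration absorbs these scales per tree, which is exactly
why the parameters are estimated rather than fixed.

## Calibration

Uniform (box) priors follow the published prior table, with site
variants where the two archetypes differ (acclimation slope, PPFD
saturation, stem modulus) and scope metadata recording which parameters
are per-tree or per-tree-year (independent blocks, no partial pooling).
The data model is iid Gaussian per stream: modelled transpiration
against the lag-aligned, leaf-area-normalised sap flow, and modelled
against observed SRD; the residual SDs are estimated nuisance
parameters with wide uniform priors scaled to the data (fixed SDs are
supported via `ErrorModel`). The sampler is an adaptive population
MCMC: an ensemble of chains evolving by differential-evolution
proposals (80%) mixed with snooker updates (20%), the proposal
geometry adapting to the posterior through the ensemble itself;
proposals outside the prior box are rejected. Runs are bit-reproducible
given a seed. MAP is the sampled vector of maximal log-posterior (first
occurrence on ties); predictive 99% credible bands resample 9000
post-burn-in parameter vectors (with replacement if fewer are
available) and add observation noise before taking the 0.5%/99.5%
quantiles per step. Split-R̂ diagnostics come from `arviz`. Burn-in
defaults to the first half of iterations.

For the likelihood's hot path, intermediates that the estimated subset
cannot affect (soil state, acclimation, light response, bark store,
data-driven cambial potential) are computed once and cached; a test
asserts exact agreement between the cached and the full evaluation.

Problem sizes: the recovery experiment in the test suite calibrates
{ψ_0, T_0, b, τ_G, E, z0, z1} plus the two noise SDs on 60-day
synthetic seasons, 5 replicates with 24 chains × 3000 iterations each —
sizes chosen so the whole study runs in minutes on one CPU while
leaving the 99% intervals' coverage criterion (≥95% of
parameter-replicate checks) intact. Flat-likelihood sanity runs use
6000 iterations thinned by 73, as Kolmogorov–Smirnov tests on less
thinned ensemble draws flag autocorrelation rather than bias.

## Analyses

Fit metrics are ordinary least squares of observed on modelled values
(slope, intercept, R²) plus the RMSE of the raw residuals. The relative
sensitivity coefficient RSC = (δy/y)/(δx/x) is computed by central
finite differences with relative step 10⁻³, undefined (NaN) where the
output is zero or a stencil arm crosses a threshold; sweeps hold the
other environmental variables at fixed means, except that VPD stays
coupled to temperature through the saturation curve (the field
covariance that shapes the assimilation response), and the soil-water
sweep holds the sap flow implied by an anchored mean drawdown
(0.3 MPa) constant so drier soil deepens the drawdown as it does in
the field. Leaf-specific production is the rectangle-rule sum of A
over a window. Phenology metrics take growth onset at the 1% crossing
of cumulative growth and cessation at a configurable quantile (99%
default); the annual cambial area increment is the annulus
π[(r₀+Δr)² − r₀²] with r₀ = DBH/2 at season start (inside-bark radius
taken as given). Correlations are Pearson with Cook's-distance outlier
screening (threshold 1) from the simple linear regression, reported
with and without flagged points. The running-maximum ("zero growth
during shrinkage") baseline is provided for comparison; it is expected
to differ from the model's growth component — rain-driven reversible
swelling inflates it, and the package's tests assert exactly that
mechanism rather than agreement.

## Limitations

No xylem–cambium resistance (potentials equilibrate instantly), no stem
water storage besides the bark, linear (turgor-independent) elastic
moduli, no boundary-layer or Farquhar-type leaf biochemistry, no cell
wall thickening or tracheid maturation pipeline, no carbon allocation
or NSC storage, and no hormonal control of phenology. The bark-influx
slope below the clamp is a placeholder. Model selection between
FM/AM1/AM2 is by fit metrics and qualitative shape only — no
information criteria are provided.
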