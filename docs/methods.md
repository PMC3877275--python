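# Methods

`growthscape` models late-summer growth of age-0 walleye pollock
(*Theragra chalcogramma*, ~65 mm SL, 2.5 g wet weight) on the eastern
Bering Sea shelf with two complementary models driven by station-level
survey inputs, and generates those inputs synthetically for a warm
(2005-like) and a cold (2010-like) regime.

## Bioenergetics mass balance

Daily maximum specific consumption is allometric with a dome-shaped
thermal response:

    Cmax = alpha_C * W^beta_C * f_C(T),   alpha_C = 0.119, beta_C = -0.46

`f(T)` is the classic Wisconsin dome: with
`V = (T_max - T)/(T_max - T_opt)`, `Z = ln(Q)(T_max - T_opt)`,
`Y = ln(Q)(T_max - T_opt + 2)`, and
`X = (Z^2/400)(1 + sqrt(1 + 40/Y))^2`, the factor is
`V^X * exp(X(1 - V))`. It equals 1 at the optimum and 0 at and above the
maximum; consumption uses (Q=2.6, 10 °C, 15 °C) and respiration
(Q=2.6, 13 °C, 18 °C). Above 15 °C, maximum consumption is zero and
growth is not estimable. This standard dome is the form that
(Q, T_opt, T_max) parameter triplets parameterize in the Wisconsin
literature; any alternative closed form can be swapped in behind
`temp_scaling` without touching the rest of the model.

Daily growth with relative foraging rate `eta` (realized consumption as
a fraction of `Cmax`):

    C   = eta * Cmax
    F   = F_a * C                (egestion, F_a = 0.15, from consumed)
    U   = U_a * (C - F)          (excretion, U_a = 0.11, from assimilated)
    SDA = D_s * (C - F)          (D_s = 0.125, from assimilated)
    R   = A_m * A_r * W^B_r * f_R(T)     (g O2 g^-1 d^-1; A_m = 2)
    G   = (C - F - U - SDA)/rho - R * O2cal / (1000 * v)

with `rho = v / e` the predator:prey energy-density ratio (fish ED `v`,
biomass-weighted prey ED `e`, both kJ g^-1 wet) and `O2cal = 13560` J
per g O2 the oxycalorific coefficient converting respired oxygen to
energy. All energy densities are carried in kJ g^-1 wet weight
throughout; station prey-ED spreads of roughly 0.5 kJ g^-1 are the
relevant scale for sensitivity runs. The model runs a single simulation
day with weight held fixed, which avoids compounding size errors and
makes growth a comparable index across stations. The energy books close
identically: `C·e = G·v + (F+U+SDA)·e + R·O2cal/1000`.

`A_m` multiplies respiration at all temperatures (a constant activity
multiplier); the alternative reading — applying it only to an "active"
fraction — is not supported by the parameter's one-line definition.

The break-even foraging rate `eta*` solves `G(eta) = 0` by Brent's
method on [0, 1]; stations where even `eta = 1` gives negative growth
have no feasible rate and report +inf. The "positive growth at half of
all stations" summary is the median of per-station `eta*`.

## Survey preparation

* CPUE `= n/(d·h)` (fish m^-2) from surface tows only; the horizontal
  trawl spread `h` defaults to 50 m (a config constant; published
  sources give the formula but not the spread, and results scale as
  1/h).
* Diet composition: station percent-volume records weighted by local
  CPUE and averaged. Main prey are selected by ranking taxa by
  descending individual percent volume, keeping every taxon at or above
  2%, and continuing below that floor until the running total reaches
  90%. This is the rule that reproduces both published diet tables,
  including a sub-2% taxon admitted to close the cumulative target.
  Ties in percent volume break alphabetically. Cumulative percentages
  are computed at full precision and rounded to one decimal for
  display. The modeling set is the union of both regimes' lists, minus
  *Neocalanus plumchrus* in the cold regime (absent from that regime's
  quantitative large-zooplankton samples).
* Copepod energy density is predicted from percent lipid by OLS
  (`ED = alpha + beta·L`, published fit alpha = 19.3, beta = 0.41,
  R^2 = 0.98). The intercept's scale follows the printed regression
  as-is; it is used only for filling taxon ED values, never mixed with
  the wet-weight station EDs without a documented conversion.
* Station prey ED is the biomass-share-weighted mean of taxon EDs over
  main prey present; zero-biomass stations are flagged and excluded
  from growth maps.
* Vertical profiles: depth-stratified net abundances are spread
  uniformly within each sampled stratum into 1-m bins, averaged across
  tows per period (day/night), and normalized. Fallbacks: a taxon
  missing from one period borrows a designated donor profile; rarely
  caught taxa get a genus-average profile; a taxon with no data gets a
  uniform profile with a warning.
* Temperatures: upper-30-m means feed the bioenergetics model; 1-m bin
  vectors truncated at min(bottom, 100 m) feed the IBM. Gaps are
  linearly interpolated; a station with no profile borrows the nearest
  station (great-circle) whose bottom depth differs by ≤25%.

## Individual-based model

100 fish per station, hourly steps, 72-h runs with only the final 24 h
analyzed (initial conditions wash out). Starting weights are uniform at
2.5 g ±30%; length follows `W = c·SL^3` calibrated to 2.5 g at 65 mm.

Hourly sequence per fish:

1. **Behavior.** Candidate depths lie within the hourly swimming range
   (1 body length s^-1, capped at 30 m h^-1). The fish takes the
   deepest candidate whose expected net energy meets maintenance plus a
   modest growth margin (default 0.005 g g^-1 d^-1) — deeper water
   means less visual predation risk — otherwise the candidate
   maximizing expected ingestion (the euphotic zone under most
   conditions). Predation risk enters only through this rule; no
   explicit mortality.
2. **Feeding.** Encounter follows a cruising-predator clearance
   `0.5·pi·r^2·v·N` per taxon. Visual range r saturates with local
   irradiance (Michaelis response, half-saturation 5 µmol m^-2 s^-1),
   scales with prey length (60 lengths at saturation, capped at
   0.8 m), and is floored at one body length in darkness. Capture
   success is ~1 for prey below 5% of fish length, declines linearly
   to 0 at 25%, and is zero for prey wider than the gape
   (0.08·SL). Ingestion fills a gut of 6% body weight; digestion
   empties 50% of gut content per hour; digested supply counts toward
   growth only up to the hourly pro-rated bioenergetics `Cmax` — this
   cap is what keeps IBM growth structurally at or below the
   mass-balance maximum.
3. **Losses.** Egestion, excretion and SDA are taken from digested
   supply with the bioenergetics proportions; respiration uses the
   temperature of the occupied depth bin; vertical movement adds up to
   10% of standard metabolic rate at full displacement, scaled
   proportionally.

Light: sinusoidal surface irradiance (noon maximum 1500 µmol m^-2
s^-1) over a 07:00–23:30 day window, night floor 1e-6, attenuated as
`E0·exp(-kz)` with k = 0.18 m^-1. Prey fields switch from day to night
vertical profiles when *surface* irradiance crosses 1 µmol m^-2 s^-1
(inclusive on the day side); keying on surface light keeps the whole
column consistent and the switch deterministic.

The exact published forms for visual range, capture, gut dynamics and
swimming speed live in the IBM literature cited by the source study and
are not printed there; each is isolated behind one configurable
function with the defaults above.

Each run records, alongside growth, a structural ceiling
(`eta1_bound`): the mass-balance `eta = 1` growth accumulated over the
fish's realized hourly weights and temperatures. Simulated growth can
never exceed it. Comparing instead against `eta = 1` growth at the
realized *mean* temperature is exact only for isothermal columns, since
the thermal response is nonlinear over a migrating fish's exposure.

## Sensitivity and comparison machinery

* Pooled SD: regime means are removed station-wise; the SD of the
  residuals uses n − (#regimes) degrees of freedom.
* ±1 SD perturbations of W, T, prey ED and fish ED report per-station
  growth deltas and min/mean/max rows; `eta` stays at 1 so scenarios
  compare maximum growth potential. Stations pushed past 15 °C are
  non-estimable and excluded from the summary statistics.
* Monte Carlo (n = 1000, seeded) draws W or fish ED from a normal with
  the observed mean and SD, truncated below at 1% of the mean to avoid
  nonphysical negatives.
* Model comparison: per-station difference field (bioenergetics −
  IBM), regime percent reduction `100·(1 − mean_IBM/mean_bioen)`
  (kept at full precision, rounded to integer percent for display),
  and the break-even `eta` with its implied reduction `100·(1 − eta)`.

## Synthetic scenario generator

No station-level field data from the underlying surveys were released,
so the generator builds bundles with the *structure* of the two
regimes; none of its distributions are estimates of real fields.

* **Stations** are uniform over a shelf-like lon/lat box; bottom depth
  increases offshore, defining inner (<50 m), middle (50–100 m) and
  outer (100–200 m) domains.
* **Temperature**: station upper-30-m means are normal around the
  regime target (8.8 °C warm, 7.6 °C cold; SD 1.0) and recentred so
  the bundle mean hits the target exactly. Inner-domain columns are
  fully mixed; stratified columns are two-layer with a logistic
  thermocline (15–30 m). A configured fraction of stations (0.55 cold,
  0.10 warm) gets cold-pool bottom water (<2 °C); the fraction is
  realized among stratified stations, since a mixed column at the
  regime mean cannot hold sub-2 °C bottom water.
* **Prey**: taxon biomasses are log-normal around regime composition
  weights times a station total (0.03 g m^-3 mean, higher inshore).
  Warm weights favour small copepods; cold weights favour euphausiids,
  *Calanus* and *Neocalanus*. The trait table is a synthetic stand-in
  mimicking the published supplement's structure (stage, length,
  width, individual biomass, ED per regime, with five taxa sharing a
  single ED across regimes); its EDs were chosen so warm bundles
  average ≈3.7 and cold ≈4.5 kJ g^-1 — the ordering, not the values,
  is the asserted contrast.
* **Vertical profiles**: truncated-Gaussian depth preferences per
  taxon and period; euphausiids deep by day and shallow by night
  (strong diel migration), Centropages-like taxa uniform in both
  periods.
* **Fish**: catch follows a thinned Gaussian intensity — broad and
  middle/outer-centred in warm, concentrated over the southern shelf
  in cold — with zero-catch stations away from the centre; weights and
  energy densities are normal around regime means (1.97/2.39 g;
  3.92/5.29 kJ g^-1). Diets are Dirichlet-noised local biomass shares.

What the generator does **not** emulate: real bathymetry and station
maps, advection and drift, fronts, observation error in nets, and any
covariance between temperature and prey fields beyond the domain
gradients. Passing regime-contrast tests therefore shows the models
respond correctly to the documented structure, not that the synthetic
fields match the 2005/2010 surveys; published table values are not
reproduction targets.

## Problem sizes and numerics

Default test and demonstration runs use 20–30 stations, 100 fish and
72-h IBM horizons; regime-contrast checks use 20 seed replicates of
30-station pairs. The eta solver brackets on [0, 1] with 1e-12
tolerance; the thermal dome is clamped to exactly 0 at and above T_max;
depth bins are half-open 1-m intervals indexed from the surface;
behavior ties resolve to the shallowest maximizing depth and equal diet
percentages order alphabetically. All randomness flows through
`numpy.random.default_rng` seeds carried in configs and manifests; a
fixed config reproduces byte-identical bundles.

## Known limitations

* The IBM's foraging constants are literature-style defaults, not
  fitted values; absolute IBM growth and depth levels are indicative
  only (the bioenergetics-vs-IBM *reduction* pattern is the robust
  output).
* The bioenergetics model ignores within-day temperature exposure
  (upper-30-m mean only) and multi-day weight dynamics.
* The ED–lipid regression is implemented and tested by parameter
  recovery on synthetic pairs; the original copepod samples are not
  available.
* Percent reductions depend on regime means and are sensitive to
  station sets when means approach zero.
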