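# Methods

## Scope and data flow

`milletqual` implements the grain-quality layer that sits on top of a daily
crop growth simulation: it does not model phenology, photosynthesis, soil
water or nitrogen uptake. Its inputs are the daily post-anthesis state a
crop model already produces — aboveground and vegetative dry weight, grain
nitrogen accumulation, actual/potential transpiration, and actual, critical
and minimum plant nitrogen concentrations — plus two scenario scalars, the
panicle density SP (spikes/ha) and grain number per panicle Ng. Day 0 is
anthesis and carries the baseline state for the day-1 increments; "the i-th
day after anthesis" means `day_index = i ≥ 1`.

## Model components and assumptions

**Stress factors.** `f(W) = Ta/Tp` clamped to [0, 1]; when `Tp = 0` the
factor is 1 (no evaporative demand implies no stress — the standard
crop-model convention). `f(N) = (ANP − MNP)/(CNP − MNP)` is clamped on both
sides: the upper clamp is part of the definition, the lower clamp at 0 is
an implementation choice that keeps the enzyme-activity product and the
conversion factor inside their documented ranges when the plant nitrogen
concentration falls below the minimum. Ta/Tp are taken as the crop model's
plant transpiration pair; whichever water-stress ratio the input series
carries is used as-is.

**Protein.** NPF uses the same-day stress minimum with no smoothing or lag
(the formulation has no memory), and the anthesis day is evaluated too so
cumulative outputs start at day 0. Only accumulation (kg/ha) is modeled,
not protein concentration or fractionation.

**Carbon supply.** The two-branch supply switches on `GDD_i ≥ GDDₘ`
(boundary assigned to the post-onset branch, consistent with the lifecycle
factor's decline starting strictly after its peak). Raw increments can be
negative — senescing canopy before the onset, vegetative regrowth after —
and are floored at 0 because the Michaelis–Menten substrate must be
nonnegative; `carbon_supply(..., debug=True)` retains the unfloored values.
There is no carbon carry-over: each day's substrate comes from that day's
fluxes only, and unconverted carbohydrate does not pool. No sucrose→starch
stoichiometric factor is applied.

**Enzyme activity.** `Eact` is the product of four factors in [0, 1]. The
lifecycle factor `f(GDD)` is clamped to [0, 1] defensively; with the
calibrated parameters (γ·GDDₘ = 0.512 < 1) the exponential branch peaks
below 1 and the clamp is inert. The cardinal-temperature response uses
half-open intervals with sine ramps and is continuous at all four
breakpoints (7, 22, 27, 60 °C).

**Kinetics.** `ISTR = ISTRₘ·Eact·GCA/(Kₘ + GCA)` can exceed the same-day
substrate at small GCA (the formulation specifies no supply limit); an
optional `cap_rate_to_supply` flag bounds the rate by GCA for users who
want strict mass balance. It defaults to off, the literal reading.

**Partition.** The amylose ratio RA is treated as a fraction in [0, 1]
(the accumulation equations multiply by RA with no /100, so the
occasionally seen "%" labeling is dimensionally inconsistent; the fraction
reading is used and documented). RA := 0 at GDD = 0 to avoid ln(0), and the
partition is applied to the cumulative starch pool, the literal form of the
equations, rather than incrementally. Amylose + amylopectin equals total
starch to floating-point precision on every day by construction.

## Parameters

| Parameter | Meaning | Unit | Default |
|---|---|---|---|
| NPF₀ | baseline N→protein conversion | – | 5.83 |
| δ | stress-dependent NPF correction | – | 0.18 |
| IGSA₀ | initial per-grain starch | mg | 0.1 |
| ISTRₘ | max per-grain synthesis rate | mg/day | 1.2 |
| Kₘ | Michaelis constant | mg/grain | 0.7 |
| GDDₘ | anthesis→peak amylase thermal time | °C d | 256 |
| γ | amylase thermal-time sensitivity | (°C d)⁻¹ | 0.002 |
| Tb, Tol, Toh, Tm | cardinal temperatures | °C | 7, 22, 27, 60 |
| α | amylose-ratio ln(GDD) scaling | – | 0.4 |
| β | amylose-ratio baseline correction | – | 2.1 |

The thermal-time base temperature is not part of the published parameter
set; the package defaults to 10 °C (the CERES convention for millet) with
daily increments floored at 0 and no upper cutoff, configurable wherever
GDD is computed.

## Synthetic scenario generator

The generator emulates the *qualitative* behavior of a crop model's daily
outputs so the whole pipeline is testable without one: a logistic
aboveground biomass curve rescaled to hit its anthesis and final values
exactly; a vegetative pool equal to the canopy until a remobilization onset
day, then releasing a configured fraction of its onset value along a
smoothstep (so the grain-mass proxy `topwt − vwt` is nondecreasing);
logistic grain-N accumulation; a sinusoid-plus-Gaussian-noise temperature
series; gently declining critical/minimum nitrogen dilution curves with the
actual concentration riding the critical curve outside stress windows
(hence `f(N) = 1`) and depressed toward the minimum inside them; and a
constant 4 mm/day transpirative demand with the actual/potential ratio
dropped inside drought windows.

Defaults sketch a plausible rain-fed foxtail millet stand: 45 days
anthesis→maturity, biomass 6→12 t/ha, 25 % of vegetative dry weight
remobilized, grain N to 100 kg/ha, 3.5·10⁵ spikes/ha × 5000 grains/spike,
21 ± 2 °C grain filling (≈ 11 °C d/day above the 10 °C base, ≈ 500 °C d per
season — commensurate with the species' grain-filling thermal time), and a
remobilization onset at day 21, where the default season's thermal time
crosses GDDₘ = 256 °C d. These are plausibility anchors chosen once, not
fits to any dataset. What the generator does **not** emulate: weather-file
realism (radiation, rainfall), soil water/N balances, biomass noise,
pre-anthesis history, or genotype-by-environment variation in the driver
curves. Tests that pass on synthetic scenarios therefore certify the
quality layer's numerics and calibration machinery, not the realism of any
particular crop simulation feeding it.

Observations are sampled every `sampling_interval` days plus the final day
(emulating destructive spike sampling every 7–10 days), with multiplicative
Gaussian noise of a given coefficient of variation, floored at 0.

## Calibration

Calibration is staged to match the model's one-way dependencies: protein
(NPF₀, δ) first, then the starch kinetics (IGSA₀, ISTRₘ, Kₘ, GDDₘ, γ) with
cardinal temperatures held fixed as model constants, then the partition
(α, β) with the starch stage frozen. Objectives are RMSE between simulated
and observed values at the sampled days (exact day matching, no
interpolation); the partition stage minimizes the equally weighted sum of
the amylose and amylopectin RMSEs.

The global search is a real-coded genetic algorithm: tournament selection
(size 3), BLX-0.5 blend crossover (rate 0.9), per-gene Gaussian mutation
(rate 0.1, σ = 5 % of each bound range), elitism 2, population 50 ×
100 generations by default; all randomness flows through one seeded
generator, so runs are exactly reproducible. Each stage then refines the
best candidates with bounded least squares (scipy's trust-region
reflective), the usual memetic hybrid: the GA locates the basin while the
refinement descends to machine precision, which a mutation-kernel-limited
GA cannot do on a cone-shaped RMSE surface. For the starch stage the
objective is discontinuous in GDDₘ wherever it crosses one of the season's
daily thermal-time values (the day classification flips), so the refinement
runs separately within each inter-day GDDₘ bin — where the objective is
smooth — and keeps the best. The partition-stage refinement stacks the two
residual vectors; its reported objective is always the summed-RMSE form.

Default bounds bracket the calibrated values: δ ∈ [0, 1], NPF₀ ∈ [5, 6.5]
(spanning the cereal literature range), IGSA₀ ∈ [0, 0.5], ISTRₘ ∈ [0.1, 5],
Kₘ ∈ [0.05, 5], GDDₘ ∈ [50, 600], γ ∈ [10⁻⁶, 0.01] (the lower bound kept
strictly positive since γ = 0 is degenerate), α ∈ [0, 2], β ∈ [0, 5].
Candidates with GDDₘ at or beyond the scenario's maturity thermal time are
structurally infeasible and receive a large finite penalty rather than an
exception, so the GA may explore the full box. Parameters calibrated onto a
bound are flagged with a warning note. ISTRₘ, Kₘ and γ can trade off on
smooth trajectories, so starch-stage success is judged by equivalent fit
(objective value), not parameter match. A scenario whose nitrogen stress
annihilates the amylose ratio on every sampled day leaves α and β
unidentifiable; the result carries an explicit degeneracy note.

## Evaluation

MRD = mean((P−O)/O)·100 %, RMSE in the variable's units, NRMSE =
RMSE/mean(O)·100 %, binned excellent < 10 % ≤ good < 20 % ≤ moderate
< 30 % ≤ poor (boundaries belong upward). Pairs with O = 0 are undefined
under MRD and are excluded with a logged warning instead of erroring, so an
anthesis-day zero does not break an otherwise valid comparison.

## Numerical choices and degenerate inputs

- All clamps are hard (`np.clip`); ties at piecewise boundaries are
  assigned as stated above (supply branch: boundary post-onset;
  temperature response: half-open intervals).
- The quality CSV is written at full repr precision; read-back reproduces
  every value to better than 1e-9.
- An empty temperature series, inverted nitrogen thresholds
  (CNP ≤ MNP), negative transpiration, stress factors outside [0, 1],
  invalid cardinal ordering and GDDₘ ≥ GDD_AM all raise `ValueError`s;
  series-level problems are collected exhaustively into a validation
  report rather than failing at the first issue.
- The scenario-recovery and property suites use problem sizes chosen for a
  thorough but quick default test run: 100 seeded random scenarios for the
  conservation and oracle-equivalence sweeps, 10⁴ random stress pairs for
  the NPF bounds, and one 46-day stressed scenario with 8 sampling dates
  for the three-stage GA recovery at the default 50 × 100 budget.

## Known limitations

- No carbon pooling or remobilization reserve dynamics; supply is
  same-day only.
- No pre-anthesis stress memory; stress acts instantaneously through the
  daily factors.
- Protein and starch are independent given the driver series (no
  competition for assimilate or N).
- The partition equation applied to the cumulative pool can revise
  previously deposited starch between amylose and amylopectin as RA drifts;
  this is the literal cumulative form and is retained as such.
- The generator's functional forms are idealized; calibration results on
  real crop-model output will inherit whatever biases that model has in
  biomass, nitrogen and transpiration.
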