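# Methods

## Model structure

`thermofish` simulates one individual fish as a two-compartment energy
budget in the tradition of physiologically structured consumer–resource
models. Structural mass *x* (bones, vital organs) is irreversible; reserve
mass *y* (fat, muscle, gonadal tissue) buffers maintenance deficits and
funds reproduction. Total mass is *w = x + y*; the model's body condition
is *y/x*, and Fulton's index *100·w/L³* is exposed for comparability with
survey data. Standardized mass *m(x) = x(1 + q_j)* — structure plus
reserves filled to the juvenile ceiling, excluding adult gonad build-up —
is the size measure for length (*L = λ1 m^λ2*) and intake allometry.

Daily energy flow (g biomass-equivalents per day):

- intake *I = d1 m^{d2} · r_a(w, T) · R_l*, with feeding level
  *R_l ∈ [0, 1]* a fixed resource proxy (1 = enough for maximum growth,
  0 = starvation);
- acquired energy *E_a = k_e I* (conversion efficiency *k_e*);
- maintenance *E_m = ρ1 w^{ρ2} · r_m(w, T)*;
- net energy *E_g = E_a − E_m*.

A surplus is split by the κ-style allocation fraction
*f = (y/x)²/((1+q)q²)* below the stage-specific condition ceiling *q*
(juvenile *q_j*, adult *q_a*), plateauing at *1/(1+q)*; the quadratic
branch means a starved fish rebuilds condition before growing structure.
The two branches meet continuously at *y/x = q*. A deficit is drawn
entirely from reserves; structure never shrinks. Death occurs when
reserves reach zero (starvation) or at the species' maximum lifespan.

## Thermal performance

Each process rate is multiplied by the classic dome-shaped bioenergetics
temperature factor

    r = V^X · exp(X (1 − V)),   V = (T_max − T) / (T_max − T_opt),

with steepness governed by a Q10-like parameter *Q* through
*W = (T_max − T_opt) ln Q*, *Y = (T_max − T_opt + 2) ln Q*,
*X = W²[1 + √(1 + 40/Y)]²/400*. The optimum, the upper (lethal) limit and
*Q* are power laws of total mass with negative exponents, so the thermal
window of both intake and maintenance slides toward colder water as the
fish grows. *r* equals 1 at *T_opt* and 0 at *T_max*; above *T_max* it is
clamped to 0 (a fractional power of a negative *V* is undefined, and the
curve's semantics there are "beyond the lethal limit"). Below the optimum
the formula is used as-is and decays smoothly — there is no lower clamp.
The factor is evaluated in log space (`exp(X(ln V + 1 − V))`), which is
exact and keeps the cold tail (*V ≫ 1*) numerically stable; an
independent, deliberately naive formula-by-formula implementation
(`thermofish.fixtures.brute_force_thermal`) is used in the test suite to
cross-check the production path to 1e-12 relative tolerance.

By default all thermal sizes are evaluated at total mass *w = x + y*; a
`thermal_mass_basis="standardized"` scenario switch evaluates them at
*m(x)* instead. The two differ only for adults holding gonadal reserves
above the juvenile ceiling and for starved individuals; in the shipped
scenarios the choice moves emergent outcomes by at most a few percent.

## Environment and time conventions

A model year is a 250-day growing season; the off-season does not exist
on the simulation clock (no feeding, no maintenance, no aging beyond the
year count — physiology is treated as dormant). Age is therefore reported
as `age_days / 250` in model years. Water temperature follows
*T(t) = T_mean + a sin(2π(t + ω)/GS)* with *t ∈ [0, GS)*; the shipped
regimes ("1980s": T_mean 12.85 °C, a 5.3; "2010s": 14.3 °C, 5.25; both
ω = 187, GS = 250) start the season at the annual minimum and peak at
mid-season (t = 125.5). Daily steps sample temperature at the start of
each day. `regime_summary` counts integer days at or below a threshold
and agrees with the closed-form arc-length of the sinusoid to within one
day; note that counts taken on monthly field data can differ from the
idealized sinusoid's by a few days, so the contraction of the cool-water
window between regimes (≈26 days at the 11 °C threshold) is the robust
diagnostic, not the absolute counts.

## Life cycle conventions

- A newborn carries total mass *w_b* split so that *y/x = q_j* exactly
  (maximum juvenile condition), the standard convention in this model
  family; any other split can be set up manually via `IndividualState`.
- Before the age at first feeding (*A_f* days) the individual is
  energetically inert by default — the egg/yolk phase neither feeds nor
  pays maintenance (`prefeeding_mode="maintenance_only"` makes it pay
  maintenance). The egg-period parameter *E_d* is stored and reported but
  does not alter the dynamics beyond being ≤ *A_f*.
- Maturity flips permanently when *L ≥ L_m*, checked once per day after
  the state update (the boundary case *L = L_m* is assigned to the adult
  stage).
- Spawning occurs on the first day of each model year from year 2 on,
  before that day's feeding step: if mature and *y > q_j x*, the full
  gonad mass *y − q_j x* is removed and converted to
  *⌊k_r (y − q_j x)/w_b⌋* eggs (*k_r* discounts the egg count, not the
  mass removed). Events are labelled by age in completed years: spawning
  at the start of model year *n + 1* is "Year *n*".
- Starvation death fires when reserves reach zero; an integration step
  that would cross zero is truncated at *y = 0*.

## Numerics

The reference integrator is explicit Euler with dt = 1 day, matching the
daily-step convention the shipped scenarios were designed around; dt is
configurable, and a classical fixed-step RK4 integrator is provided for
convergence checks (adaptive schemes sit poorly with the day-resolution
forcing and the discrete spawning/feeding-onset events). Across the full
30-scenario grid, Euler dt = 1, Euler dt = 0.1 and RK4 agree on final
length to within 0.2 % (the suite asserts 1 %). Growth from egg mass is a
stiff power-law burst — the first feeding days multiply mass a
thousand-fold — but the trajectory rapidly forgets its early history, so
the daily step converges despite large early per-step increments.

## Shipped parameterizations

The five species files transcribe published physiological estimates:
egg mass, condition ceilings, conversion efficiencies, maturation length,
length and intake allometries, maintenance allometry, and per-process
thermal scaling coefficients. Registry load validates the schema and the
physiology (*T_max > T_opt* and *Q > 1* from egg mass to a 10 kg cap);
files round-trip bit-exactly through `save_species`. Maximum lifespans
are not part of the physiological tables; the shipped values (cod 25,
herring 12, rockling 4, sprat 6, mullet 25 model years) are documented
approximations of reported longevities and are configurable per file.

## Synthetic observations

`make_fake_observations` emulates the *shape* of survey length-at-age
tables (species, age, length, period, source) by scattering lognormal
noise around a simulated cooler-regime growth curve at moderate feeding.
It reproduces none of the sampling structure of real surveys (gear
selectivity, cohort mixing, measurement binning, spatial heterogeneity),
so tests built on it demonstrate plumbing and self-consistency — e.g.
that noise-free observations fall inside the feeding-level envelope —
not agreement with field data.

## Emergent behaviour and known limitations

With the shipped parameterizations the model produces the expected
qualitative regime: feeding level dominates growth everywhere; cod never
reaches its 62 cm maturation length and never reproduces; rockling halts
growth mid-season when temperatures overshoot its size-specific optimum
and resumes in autumn, spawning exactly once; sprat and mullet lose
late-life fecundity under the warmer regime, with reproduction ceasing
one to several years earlier; and herring lifetime fecundity under the
cooler regime is ≈68 000 eggs at moderate feeding and ≈37 000 at low
feeding.

Two structural caveats matter when interpreting survival outcomes:

1. **Maintenance near its thermal maximum.** The dome response sends
   *r_m → 0* as *T → T_max,m*, i.e. maintenance costs vanish just below
   the metabolic lethal limit. Herring's steep metabolic size exponent
   (*v_max = −0.05*) brings *T_max,m* below the summer peak at roughly
   100 g, so large herring are "frozen" (zero intake, zero maintenance)
   rather than starved through the warmest weeks. Starvation mortality of
   large individuals at peak temperatures is therefore much weaker than a
   monotone (e.g. exponential-to-plateau) maintenance response would
   produce. This is a property of the response formulation, kept as
   specified rather than silently re-shaped.
2. **Knife-edge survival.** Several scenarios sit close to the starvation
   boundary (e.g. cod under the warm regime draws its condition down to
   ≈0.13 in its second summer before recovering). Small changes in
   parameter values, in the maintenance response above its optimum, or in
   start-of-season conventions can flip such scenarios between death and
   survival, and shift reproductive spans by a year. Emergent survival
   ages and last-reproduction years should be read with that sensitivity
   in mind.

Out of scope by design: population feedbacks and density dependence,
dynamic resources, oxygen/aerobic-scope mechanics, stochastic mortality,
and fishery effects.
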