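# Methods

## The model

`tunaforage` treats a bluefin tuna larva as a cruising visual predator in a
warm, strongly lit, oligotrophic mixed layer. Three processes close the
budget:

1. **Encounter.** The larva swims at `swim_bl_per_s` (default 3) body
   lengths per second and scans the upper half of its visual field, using
   the sea surface as background contrast, so the clearance rate for a prey
   type is the half-disc swept per unit time, β = ½πR²V_L (m³ h⁻¹).
   Detection distance R is taken proportional to both prey length
   (bigger items subtend more of the retina) and larval length (eye size
   and acuity grow with the body): R[mm] = c·l_prey·L. The optical constant
   c aggregates water clarity, contrast and acuity; it is not measured
   directly but solved from a single anchor (below). At night R = 0: the
   larvae do not feed in darkness.
2. **Ingestion.** i = P·β·N·W_prey (mg dw h⁻¹), linear in ambient density N
   — no handling time or gut saturation. Capture probability P is 1 for
   nauplii at all sizes; for larger, evasive prey (cladocerans, copepods)
   it ramps linearly with larval length between `capture_ramp_start`
   (3.0 mm, first feeding) and `capture_ramp_end` (7.5 mm, post-flexion).
   The ramp endpoints are a design choice: they make the post-flexion stage
   fully competent while first-feeding larvae can barely take large prey.
3. **Metabolism and growth.** Routine metabolism is the allometric oxygen
   consumption 0.404·W^0.994 µmol O₂ h⁻¹ at the 26 °C reference, converted
   to mg dw h⁻¹ through an ordered factor chain (32, 0.88, 12/34, 100/45000 —
   O₂→µg, protein fraction, carbon:protein, dw:carbon) and scaled by
   Q10 = 2. The chain is stored as an explicit tuple so every factor is
   auditable and individually overridable. The hourly daylight budget is
   SGR·W = α·Σi − R with assimilation α = 0.77.

The daily rate multiplies the hourly rate by the 15-h photoperiod and is
capped at the temperature-driven ad-libitum ceiling
SGR_T = 0.0418·T − 0.8355 day⁻¹ fitted to rearing experiments at 22–28 °C.
Outside that range the line is an extrapolation and the package warns
rather than errors. We implement the ceiling as a hard `min` rather than a
gut-capacity state variable; gut dynamics, specific dynamic action and
temperature-dependent assimilation are deliberately out of scope.

**Night-time bookkeeping.** Whether the laboratory ad-libitum growth rates
already absorb night metabolism is not knowable from the available
descriptions, so the accounting is a switch. The default (`daylight`)
accrues metabolism only over the feeding hours when converting to a daily
rate; `full_day` additionally subtracts (24 − D)·R/W. The default
reproduces the ≈2:1 ratio between full-growth and maintenance thresholds
seen in the published threshold tables; `full_day` raises maintenance
thresholds by about a third.

## Calibration

All stated proportionalities are preserved but the absolute scale of
detection lives in one constant c. `calibrate_detection` solves it in
closed form so that the critical density of the anchor configuration —
stage F0 (4.8 mm), nauplii only, 22 °C, full growth at 4000 m⁻³ — is met
exactly:

    c = √(2·i_req / (π·V_L·N·W_prey·P)) / (l_prey·L)  = 7.3367 per mm²

With defaults this gives F0 nauplius detection at 5.3 mm, rising to 8.3 mm
at F3 — a few larval body lengths, plausible for a high-contrast target in
clear water. Every other threshold (other stages, temperatures, prey) is
then a genuine out-of-sample prediction; the test suite checks twenty of
them against published order-of-magnitude values within ±25%, a band chosen
because those values are printed as rounded "order of" figures.
Recalibrating from any model-generated threshold recovers the same c
(tested to 1e-9), so the anchor choice is immaterial up to the quality of
the anchor value itself.

**Capture-probability mode.** Published single-prey threshold tables for
cladocerans and copepods are numerically consistent with P ≈ 1 at *all*
stages, which contradicts a literal 0→1 ramp at pre-flexion. Both
behaviours are provided: `assume_full_capture=True` (used for the
single-prey threshold tables and their tests) and the ontogenetic ramp
(default for station assessment). Neither is asserted as the single correct
reading.

## Critical densities and limitation

Because ingestion is linear in density the threshold is closed-form,
N* = i_req/(P·β·W_prey), with i_req = (g + R·24/D·[full_day])/α and
g = SGR_T·W/D for full growth or 0 for maintenance. When P = 0 (large prey,
pre-ramp larva) the threshold is reported as +inf rather than raising. The
numeric route — root-finding on the growth budget itself — agrees with the
closed form to 1e-9 over random configurations (a standing test), so the
closed form is convenience, not an approximation.

Useful exact consequences, both tested: thresholds for two prey scale as
N*_A/N*_B = (W_B·l_B²)/(W_A·l_A²) under equal capture — cladoceran
thresholds sit ≈815× (three orders of magnitude) below nauplii thresholds —
and swapping the 0.15 mm/0.11 µg nauplius for the 0.3 mm/0.5 µg sensitivity
variant divides nauplii thresholds by exactly 200/11 ≈ 18.2.

The station assessment evaluates four diet scenarios (each prey alone,
all combined) at every station and stage, using the station's mixed-layer
temperature (default 24.5 °C with a warning when missing). Limitation is
FLI = realized/ad-libitum SGR < 1; failure to cover metabolism
(SGR < 0, starvation) is reported separately because the two thresholds
differ by roughly a factor of two in density.

## Synthetic surveys

The generator emulates the two 17-station Balearic Sea summer surveys:
lognormal prey abundances (the printed ranges are strongly right-skewed
relative to their means), truncated-normal mixed-layer temperatures, a
fixed number of stations with no cladocerans and no bluefin larvae (3/3 in
the 2020 profile, 1/2 in 2022), uniform cosmetic coordinates in the survey
box, and independence between larval and prey densities (none was found in
the field). Printed means/SDs are read as describing prey-present stations,
since the printed ranges start at 1 m⁻³ and therefore exclude the absence
stations.

Numerical detail: the lognormal shape σ comes from the plain mean/SD moment
match; samples are then clipped to the printed range, which would bias the
mean (≈−2% for 2020 nauplii), so the location parameter is solved with
Brent's method for the *post-clipping* mean to equal the printed mean. The
SD consequently carries a modest truncation bias (clipping shrinks it; the
generator reproduces means exactly in expectation, SDs only approximately).
The temperature location is solved the same way under truncation. When the
requested sample size equals the real survey size (17) the absence count is
forced exactly; at other sizes it becomes the equivalent Bernoulli
probability.

What the generator does **not** emulate: spatial autocorrelation, eddy
structure, CTD profiles, between-variable correlations beyond independence,
or inter-annual dynamics. Tests that pass on synthetic surveys therefore
demonstrate pipeline correctness and the qualitative diet-scenario result
(nauplii-only diets limiting nearly everywhere, copepod-bearing diets not),
not fidelity to any particular cruise.

## Numerical choices and degenerate inputs

- Closed forms throughout; the only iterative steps are Brent solves in the
  generator and the oracle root-finding in tests (tolerance 1e-12).
- The cap flag is set when the uncapped daily SGR is ≥ the ceiling, so
  realized SGR equals the ceiling exactly iff the flag is set, and FLI is
  exactly 1.0 there (no floating-point shortfall).
- Empty diets and zero densities are valid (starvation); negative densities
  raise; malformed survey rows are reported with row and column and
  skipped; missing prey columns are treated as absence with a warning.
- FLI is NaN when the ad-libitum ceiling is non-positive (below ≈20 °C,
  outside the model's intended range).
- All station CSVs are written at full double precision; rounding happens
  only in log messages.

## Problem sizes

Default analyses are closed-form algebra: the full threshold grid, the
17-station assessment and the acceptance script each run in well under a
second. Statistical tests of the generator use 4000–10000 stations, which
keeps moment checks at 2-standard-error resolution while the whole suite
runs in a few seconds.

## Known limitations

- One optical constant absorbs all of acuity, contrast and turbidity; the
  model cannot separate water clarity from eye development, and the
  detection ontogeny is exactly linear in larval length by assumption.
- No handling time, gut capacity, density-dependent competition, swimming
  cost modulation, or piscivory (relevant after post-flexion).
- The linear SGR ceiling extrapolates badly outside 22–28 °C.
- Thresholds inherit the ±25% looseness of the rounded values the model is
  compared against; the calibration anchor value itself is one of those
  rounded figures.
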