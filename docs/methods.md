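# Methods

## Scope and data model

The package projects the national burden of primary total knee (TKR) and
hip (THR) replacement performed for osteoarthritis (OA) from four inputs:
a procedure-level registry extract, an age/sex-stratified population
series (observed and projected), two-point overweight/obesity prevalence
surveys per sex, and a per-admission unit-cost schedule. Revision surgery,
post-operative complication costs, sports-injury risk, and non-OA
indications are out of scope throughout.

Records carry age (or an age group), sex, procedure year, joint, procedure
class, diagnosis, hospital sector (public/private), setting
(metropolitan/regional) and side. Age groups are half-open bins [0, 40),
[40, 70), [70, ∞), labelled `<40`, `40-69`, `70+`; age group is derived
from age at procedure when both are supplied and must agree. Inclusion
requires `procedure_class = primary` and `diagnosis = osteoarthritis`.

### Bilateral collapsing

Procedure-month data are generally unavailable in annual registry
extracts, so whether two same-year joint replacements were staged or
simultaneous cannot be observed. The package takes the conservative
(cheaper) reading: two or more procedures for the same patient, in the
same year, on the same joint, within the same hospital sector form one
simultaneous bilateral admission. Groups larger than two — which the rule,
stated for pairs, does not anticipate — are still collapsed to a single
admission, with a warning. Two design points:

* the collapsing key includes the joint; two same-year procedures on
  *different* joints are never grouped (an open interpretive point — this
  is the stricter reading);
* collapsing affects **costing only**. Incidence counts and rates always
  use procedures, never admissions.

Conservation is an enforced invariant: total procedures across admissions
equal the filtered record count.

## Incidence projection

Stratum counts are converted to rates per 100,000 as
`1e5 × count / population` cell-wise; an aggregate year rate divides the
total count by the total denominator population. The per-100,000
denominator is whatever population series is supplied (the package's
reports use the series' full coverage); because published aggregate rates
of this kind are sensitive to the denominator choice (total vs adult
population), the denominator is an explicit input rather than a baked-in
constant.

**Scenario 1 (constant rate)** multiplies base-year stratum rates by the
projected stratum populations for every year through the horizon. It is
exactly linear in the population: doubling every population cell doubles
every projected count.

**Scenario 2 (continued growth)** fits, per joint, a Poisson log-linear
model of stratum-year counts with

* offset `log(population/1e5)` (so `exp(linear predictor)` is a rate per
  100,000),
* treatment-coded age group and sex main effects,
* a linear calendar-year term centred at the base year (the projection
  anchor).

The offset convention models the *rate*, which is what is being projected;
a no-offset pure-count variant is available behind `use_offset=False` for
comparison, since either reading is defensible for this class of published
projection. Year-by-age and year-by-sex interactions exist behind an
`interactions` flag but are off by default (main effects only); models are
fitted separately per joint with no joint interactions. Fitting uses
statsmodels' GLM/IRLS; a non-converged or non-finite fit refuses to
project. With the year coefficient forced to zero, Scenario 2 reduces to
Scenario 1 applied to the fitted base-year rates (verified cell-wise to
1e-8 relative).

Projected counts are kept fractional internally; rounding (half away from
zero) happens only in report columns and headline totals. Percent growth
is `100 × (n_final − n_base)/n_base`, reported to the nearest integer.

## Obesity sensitivity analyses

Combined overweight/obesity prevalence (BMI ≥ 25, % of adults) is anchored
at two measured surveys per sex. Survey waves spanning two collection
years anchor at the **first** year (a 2011–12 wave anchors at 2011); this
is the only convention under which the published annual increases
(0.65 pp/yr men, 0.40 pp/yr women) compound to the published 2030
prevalences (82.7% and 63.8%). The trend is the straight line through the
two anchors; extrapolation adds `trend × (target − last anchor)`,
clips to [0, 100], and reports at one decimal (survey precision),
half away from zero — built-in banker's rounding would turn 82.65 into
82.6.

The attributable fraction uses a modified Peto–Lopez form

    PAF = (P0·RR − P1·RR)/(P0·RR) = 1 − P1/P0,

in which the relative risk RR cancels. This RR-invariance is deliberately
preserved as the default (`mode="peto_lopez"`): it is the form whose
arithmetic the downstream scenario ladders follow exactly (e.g.
0.05 × 161,231 → 8,062), and it makes prevalence shifts act
proportionally on counts. The tension between citing meta-analytic RRs as
inputs and using an RR-invariant formula is a documented property of this
analysis family, not resolved here; the classical Levin form
`P·(RR−1)/(P·(RR−1)+1)`, where RR genuinely matters, is available as
`mode="levin"` for comparison but drives no scenario.

* **Increasing prevalence:** per sex, extra = base_sex × (P1/P0 − 1),
  summed then rounded. When the projection lacks sex detail the base is
  apportioned by a configured female share (the registry's base-year sex
  mix by default); the approximation is logged. Reproducing a published
  total computed with an unpublished horizon-year sex mix is therefore
  approximate at the ~0.1% level.
* **Reduction ladder (1–5%):** P1 = P0(1 − x) for both sexes, so PAF = x
  and fewer = round(x × base), rounded half away from zero at the final
  step only. Under this arithmetic the constant-rate base 65,569 gives
  656/1311/1967/2623/3278 fewer procedures; published tables of this
  analysis print 1312 and 3279 in the 2% and 5% cells, one unit above the
  half-away values — retained here as a known discrepancy rather than
  matched.
* Hip replacement is excluded from obesity adjustment by default (no
  consistent BMI–THR association is assumed); `include_hip_obesity=True`
  enables it with a warning, for exploration only.

## Costing

Admissions are priced from a (joint × sector × laterality) unit-cost
schedule; bilateral admissions are costed once at the bilateral rate,
which must be at least the unilateral rate (with the bilateral rate at
exactly twice the unilateral, collapsing is cost-neutral — a tested
coupling). Price-index inflation is multiplicative
(`cost × idx(to)/idx(from)`) and hence path-independent. Scenario cost
deltas price procedure-count changes at a blended average cost per
procedure (total cost / procedures); published deltas of this kind are
consistent with a single blended average rather than cell-specific costs,
so that is the default. Currency is an opaque label (default
`AUD-2016`).

The shipped default schedule is **synthetic**: true cost-collection cell
values are not public in the sources this package emulates, so unit costs
are back-derived from aggregate expenditure (≈ $21,100 per unilateral
admission in 2016 AUD, small private-sector loading, bilateral at 1.75×)
and shipped as an editable CSV-compatible default. The default price index
is likewise a smooth synthetic 2%/yr series. Both are placeholders for
real schedules, not estimates of them.

## Synthetic registry generator

The generator emulates the study conditions with known ground truth:

* **Counts.** Per (joint, age group, sex, year), the primary-OA count is
  Poisson with mean `rate₀ · e^{β(t−t₀)} · pop(s,t)/1e5`. Default slopes
  β are ln(2.05)/10 per year for knee and ln(1.73)/10 for hip — the
  log-linear equivalents of the observed ~105% and ~73% decade growth in
  utilisation. Default baseline rates per 100,000 (knee 1/170/700 female
  and 1/150/650 male across the three age bins; hip 3/110/500 and
  3/110/480) land near the observed national aggregate 2003 rates
  (~120/100k knee, ~85/100k hip) under the default population structure.
* **Population.** Geometric growth per stratum from an Australia-like age
  structure at **1/100 scale** (≈199,000 total in 2003), with the 70+
  group growing fastest (3%/yr vs 1–1.5%) to emulate ageing. The scale
  factor keeps full-pipeline runs in seconds while preserving all rates;
  absolute projected counts are therefore ~1/100 of national scale, which
  is why registry-scale headline totals are validated by *parameter
  recovery and structural invariants* rather than by reproducing national
  numbers.
* **Records.** Stratum counts are exploded into records with synthetic
  patient IDs. A configured fraction of procedures (0.163 knee, 0.065
  hip — observed bilateral shares) arrives as same-patient left+right
  pairs sharing sector and setting. Sector and setting are Bernoulli
  (private 0.70, metropolitan 0.65); ages are uniform within bins.
  Contamination is added on top: non-OA primaries at rate
  μ(1−f)/f (f = 0.89, the observed OA share) and revisions at 0.05μ, so
  the primary-OA filter recovers the ground-truth counts *exactly* — the
  end-to-end generate → write → load → filter → tabulate identity is a
  tested invariant.
* **Determinism.** One numpy `default_rng(seed)` drives all draws in a
  fixed iteration order; identical configs write byte-identical files.

What the generator does **not** emulate: within-patient longitudinal
structure beyond the same-year rule, staged bilateral timing, geographic
(state) structure, comorbidity, BMI at the patient level, or secular
changes in case mix. Passing tests therefore demonstrate that the
*methods* are implemented correctly and recover known parameters under the
stated stochastic model — not that real registry data satisfy that model.

## Numerical and testing choices

* All report rounding is half away from zero, cleaned at 9 decimals first
  to absorb float representation noise.
* Parameter recovery is assessed over 20 simulated decade registries at
  the default (1/100-scale) conditions; the mean fitted knee year-slope is
  required to lie within ±0.01 of the generator slope and within 2
  Monte-Carlo standard errors of it. A single replicate's sampling SE at
  this scale is ≈0.005, so the bound is a statement about bias, not about
  individual draws.
* Structural invariants (procedure conservation under tabulation and
  bilateral collapsing, laterality consistency) are exercised on 1,000
  randomised small registries plus derandomised hypothesis cases.
* Degenerate inputs fail loudly: missing population or schedule cells are
  named in the error; single-year count tables refuse a trend fit;
  non-converged models refuse to project; zero base counts refuse percent
  growth.

## Known limitations

* Point projections only — no prediction intervals, no model selection.
* The blended-average costing ignores joint/sector composition shifts in
  scenario deltas.
* The linear prevalence extrapolation has no saturation short of the
  [0, 100] clip; 19-year extrapolation from a 4-year baseline is an
  assumption inherited from the analysis design, not an estimate.
* The printed-form PAF's RR-invariance means the relative-risk input has
  no effect in the default mode; use `mode="levin"` to explore
  RR-sensitive attributable fractions.
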