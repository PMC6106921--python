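# Methods

## Model structure

The package appraises whole-service redesign options for postnatal care, not
individual care plans. A *service option* specifies, for each care category
(acuity band of mother/baby dyads), a hospital stage — length of stay in
hours, regular ward staff hours per case by grade, dedicated
feeding-and-parenting support hours — and a community stage, a list of
contacts (home visit, clinic, phone) with grade, duration and travel minutes.
Phone and clinic contacts carry zero travel by construction.

Declarative *derivation rules* map the structured stages onto the flat
design-parameter vector the scoring equation consumes (`length_of_stay`,
`staff_hours_total`, `staff_hours:<grade>`,
`dedicated_feeding_parenting_hours`, `contact_count[:<kind>]`,
`contact_minutes[:<kind>]`). The generic parameter set is therefore
configuration, not code: a deployment chooses its own levers.

## Quality scoring

For domain *j*: `s_j = 100 · Σ_i q(i,j)·r_i / Σ_i q(i,j)` with
`r_i = min(x_i/z_i, 1)`. Assumptions inherited from the linear-additive MCDA
form: effects of parameters are additive within a domain, linear up to the
maximum beneficial value `z_i`, and contribute nothing beyond it.

* **Capping.** `z_i` is a *maximum beneficial* value, so the benefit ratio is
  capped at 1 by default; otherwise over-provision would inflate quality. An
  uncapped mode (`cap=False`, CLI `--no-cap`) exists for exploration only.
* **Negative impacts.** A lever may harm a domain (e.g. earlier discharge and
  safety). Negative `q(i,j)` entries are accepted provided the domain's column
  sum stays positive (it is the normalization denominator); validation then
  warns that the 0–100 bounds no longer hold, rather than erroring.
* **Shared matrix.** One impact matrix and one `z` vector are shared across
  categories; only `x_i` varies by category. Scores are comparable across
  categories on the common 0–100 scale.
* **Aggregation.** `Σ_j w_j s_j` with weights summing to 1 (tolerance 1e-9).
  The default weights (safe 0.50, effective 0.30, timely 0.05, equitable 0.05,
  person-centred 0.10) represent a deliberated stakeholder consensus and are
  expected to be challenged — that is what the weight sweep is for. A
  service-level aggregate, when requested, is the demand-weighted mean of
  per-category aggregates (weights ∝ annual births); results are otherwise
  reported per category.

## Costing

Hospital cost is split into staff cost (ward hours × grade rate, plus
dedicated feeding/parenting hours priced at a configurable grade, default
maternity care assistant) and bed cost (stay/24 × bed-day rate including
associated infrastructure). The split is deliberate: quality tracks
staff-hours much more than bare bed-days, so a redesign can shed bed cost
without shedding staff contact. Community cost prices each contact's duration
plus travel at the grade's hourly rate; clinic contacts add a per-contact
overhead; phone contacts are duration-only. Travel is costed at the visiting
staff member's rate; mileage is out of scope. Currency is abstract. Annual
cost is linear in demand: births × per-case cost, summed over categories.

If the acuity sub-model is used to re-split community demand, the per-case
community cost of a category is rescaled by (discharged ÷ admitted) so the
additivity identity annual = births × per-case-total still holds; a category
with zero admissions but positive discharge inflow cannot be represented this
way and is a known limitation.

## Acuity transition sub-model

Acuity tends to fall during the ward stay. The sub-model is a linear decay
chain over the ordered categories (lowest to highest acuity): category *k*
transfers mass to category *k−1* at a constant per-hour rate, the lowest
category absorbs. Solved in closed form with the matrix exponential, so
simplex conservation and the zero-stay identity are exact and the high-acuity
share is non-increasing in stay; tests cross-check against an independent
0.1 h forward-Euler mass-transfer simulation (agreement within 1e-3). The
exponential form is this package's modelling choice — sites with workforce
data should re-estimate both form and rates — and the module is optional:
scoring and costing never require it.

## Comparison and sensitivity

`compare_options` recomputes both options from scratch (no cached deltas), so
A-vs-B is exactly the negation of B-vs-A. Equity-plane classification uses
strict inequalities; a zero delta on either axis is `neutral` because the
boundary semantics are genuinely undefined. The percentage saving is
100·(cost_A − cost_B)/cost_A, undefined for non-positive baseline cost.

The weight sweep perturbs each selected domain weight (defaults: safe,
effective, person-centred; deltas ±0.1, ±0.2) and renormalizes the remaining
weights proportionally — `w_j · (1 − w_new)/(1 − w_old)` — preserving their
ratios. Domain scores are weight-independent, so only aggregation is redone
per perturbation. Perturbations leaving [0, 1] are skipped with a logged
warning. The robustness flag per category is true iff the sign of the
aggregate quality delta is constant across baseline and all perturbations;
when all domain deltas share a sign this is guaranteed (any weight vector is a
convex combination). Monte Carlo propagation of input uncertainty is a
documented non-feature; the sweep functions are the extension point.

The parameter sweep writes each grid value back into the option via the
inverse of the derivation rules (stay and dedicated hours set directly,
contact counts by cloning/trimming contacts of the kind — integer values
required — staff hours and contact minutes by proportional scaling) and fully
recomputes scores and cost per row, with no cross-row state.

## Demonstration bundle

The fixture emulates an illustrative English trust: 5,200 births/year split
2000/1600/1200/400 over categories `0a`/`0b`/`1`/`2&3`; stays of 24/36/48/72 h;
midwife + maternity-care-assistant ward staffing rising with acuity; 2–4
midwife home visits (40 min + 20 min travel) plus a 15-min phone call; round
unit costs (midwife 44/h, assistant 24/h, bed-day 400, clinic overhead 6).
Five design parameters (stay hours, ward staff hours, feeding-support hours,
home visits, clinic contacts) with maximum beneficial values 72 h / 16 h /
3 h / 6 visits / 2 visits. The impact matrix encodes the qualitative pattern
that ward time and staffing chiefly protect safety while feeding support,
clinics and home visits drive effectiveness, timeliness, equity and
person-centredness; its magnitudes are synthetic. Option B applies exactly the
four-item redesign package (−20% stay; −10% regular ward staffing with +1 h
dedicated feeding support; +1 home visit, +2 for `2&3`; +1 clinic contact,
supplementing rather than replacing visits).

What the fixture does *not* emulate: any real site's calibrated impact matrix
or activity data, seasonal/stochastic demand, staff rostering constraints, or
patient-level heterogeneity within a category. Passing tests therefore
demonstrate the correctness of the machinery (normalization, capping,
renormalization, additivity, determinism), not the empirical performance of
any particular redesign. Two presentational notes: categories `0a` and `0b`
deliberately carry identical descriptions (the distinction is site-specific
and left to deployments to word); and the generator is fully deterministic —
the `seed` argument is accepted and logged for interface uniformity, but the
content is fixed, so regeneration is byte-identical.

## Numerical choices

* Equality tolerances: 1e-9 relative for weights, mixes and cost identities;
  scoring matches an independent summation oracle to 1e-12 in tests.
* Weight renormalization subtracts any sub-tolerance floating drift from the
  perturbed domain so the vector revalidates exactly.
* The decay chain clips tiny negative matrix-exponential round-off to zero and
  renormalizes the simplex.
* Degenerate inputs: zero impact-column sums, weights not summing to 1,
  missing grades/rates, unknown parameter ids and fractional contact counts
  raise typed errors naming the offender; structural problems in options are
  returned as validation reports (data, not exceptions), aggregated across the
  whole bundle on load.
* Ties in equity classification (zero delta) map to `neutral`.

## Known limitations

Two-option comparison only (no Pareto search over many options); no
optimisation of the redesign package; no probabilistic sensitivity analysis;
no discounting or capital planning; community demand re-splitting assumes
every category has admissions. Problem sizes throughout (4 categories, 5
parameters, 5 domains) reflect the intended workshop use; all computations are
instantaneous at this scale.
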