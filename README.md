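# caredesign

Multicriteria decision support for redesigning postnatal care pathways.

Postnatal care — routine care of mothers and babies in the days after birth,
first on a hospital ward and then in the community — is typically planned
service-wide, trading hospital stay, ward staffing and community contacts
against cost. `caredesign` implements a transparent appraisal model for such
redesigns, combining multicriteria decision analysis (MCDA) with a programme
budgeting and marginal analysis (PBMA) view of cost: service options are
scored against the five Institute of Medicine quality domains (safe,
effective, timely, equitable, person-centred), costed per care pathway, and
compared on the health equity impact plane. It is intended for health-service
planners, health economists and analysts supporting deliberative redesign
workshops.

## The model

A service option assigns each care category *c* (acuity bands `0a`, `0b`,
`1`, `2&3`) a hospital stage (length of stay, staff hours by grade, dedicated
feeding-and-parenting support) and a community contact schedule. Derivation
rules map these onto design-parameter values *x<sub>i</sub>*. Each parameter
has a maximum beneficial value *z<sub>i</sub>*, and an impact matrix
*q(i, j)* records its contribution to quality domain *j*. The domain score is
the normalized weighted sum

&nbsp;&nbsp;&nbsp;&nbsp;*s<sub>j</sub>* = 100 · Σ<sub>i</sub> *q(i, j)* ·
min(*x<sub>i</sub>*/*z<sub>i</sub>*, 1) / Σ<sub>i</sub> *q(i, j)*,

so a service with every parameter at its maximum beneficial value scores 100
in every domain. Domain scores combine into an aggregate Σ<sub>j</sub>
*w<sub>j</sub>* *s<sub>j</sub>* with stakeholder weights *w* (defaults: safe
0.50, effective 0.30, timely 0.05, equitable 0.05, person-centred 0.10).
Costs are kept separate from quality: hospital staff cost, bed/infrastructure
cost (bed-days × bed-day rate) and community contact cost (duration plus
travel at the grade's hourly rate, plus clinic overheads), per case and per
annum. Two options A (current) and B (redesign) are compared by differencing
fully recomputed scores and costs; each category lands in a quadrant of the
equity impact plane (quality up + cost down = "win-win"). Deterministic
sensitivity analysis perturbs selected domain weights by ±0.1/±0.2 with
proportional renormalization of the rest, or sweeps a single design parameter
over a grid. An optional decay-chain sub-model maps hospital stay to the
acuity mix at discharge into the community.

## Worked example

The bundled demonstration model describes an illustrative trust with 5,200
births a year. Option B applies a four-item redesign to option A: −20%
hospital stay, −10% regular ward staffing with more dedicated
feeding-and-parenting support, one extra home visit for every category (two
for `2&3`), and a feeding-and-parenting clinic attendance for all.

```
python examples/compare_redesign.py
```

prints

```
Per-category deltas (B - A):
          d_safe  d_effective  d_timely  d_equitable  d_person_centred  d_aggregate  d_cost_per_case  d_cost_annual quadrant
category
0a          8.72        19.73     30.19        23.11             23.27        15.27             -6.4       -12800.0  win_win
0b          7.57        19.22     30.03        23.02             22.94        14.50            -52.0       -83200.0  win_win
1           6.11        18.47     29.72        22.83             22.50        13.47           -103.2      -123840.0  win_win
2&3         7.36        21.15     31.88        32.46             27.86        16.03           -161.6       -64640.0  win_win

Service annual cost: A = 4,962,800, B = 4,678,320
Annual saving: 5.7%
```

Every care category gains aggregate quality (e.g. +16.03 for the complex-needs
category `2&3`) while costing less per case, so each row classifies as a
potential win-win; the service as a whole saves 5.7% per annum. The other
examples score a single option (`score_service.py`), test the robustness of
these gains to the domain weights (`weight_sensitivity.py` — the gains survive
all ±0.1/±0.2 reweightings), sweep one design parameter
(`sweep_home_visits.py`) and exercise the acuity sub-model
(`acuity_discharge.py`).

The same pipeline is scriptable from a shell:

```
caredesign fixture --out demo_bundle
caredesign validate --bundle demo_bundle
caredesign compare --bundle demo_bundle --out reports
caredesign sweep --bundle demo_bundle --out reports
```

Bundles are plain CSV/YAML files that workshop participants can read and edit;
all report outputs are deterministic, byte-for-byte.

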