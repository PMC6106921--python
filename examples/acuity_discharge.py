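"""Acuity at discharge as a function of hospital length of stay.

While mother and baby stay on the postnatal ward their acuity tends to fall,
so a longer stay discharges fewer high-acuity dyads into the community.  The
decay-chain sub-model makes that relationship explicit: starting from an
admission mix over the four acuity categories, it computes the discharge mix
for a range of stays, and the demand each category places on community
services once every category's own stay is accounted for.
"""

from caredesign import AcuityMix, build_fixture_bundle, discharge_demand, discharge_mix

bundle = build_fixture_bundle()
params = bundle.transition
total = sum(c.annual_births for c in bundle.categories)
admission = AcuityMix({c.id: c.annual_births / total for c in bundle.categories})

print("Admission mix:", {k: round(v, 3) for k, v in admission.as_dict().items()})
print()
print("Discharge mix by length of stay (hours):")
for stay in (0, 12, 24, 48, 72):
    mix = discharge_mix(admission, stay, params)
    cells = "  ".join(f"{c}={mix[c]:.3f}" for c in params.order)
    print(f"  stay {stay:>3} h   {cells}")
print()
demand = discharge_demand(bundle.options["A"], bundle.categories, params)
print("Annual community demand implied by option A's per-category stays:")
for cat in params.order:
    admitted = next(c.annual_births for c in bundle.categories if c.id == cat)
    print(f"  category {cat:<4} admitted {admitted:6.0f}  "
          f"discharged into community {demand[cat]:8.1f}")
print("\nMass only moves toward lower acuity, so shortening stays (as a "
      "redesign does) shifts more high-acuity care into the community.")
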