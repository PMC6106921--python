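"""Illustrative demonstration bundle: a current service and one redesign.

Option A sketches a typical English trust's postnatal service (about 5,200
births a year, short ward stays, a small number of midwife home visits).
Option B is derived from A by exactly four changes — the redesign package the
tool is meant to appraise:

* hospital length of stay reduced by 20% in every category;
* regular ward staffing reduced by 10%, with dedicated feeding-and-parenting
  support hours on the ward increased (here: +1 hour per case);
* one extra home visit for every category, two extra for category 2&3;
* every mother attends a feeding-and-parenting support clinic (one extra
  clinic contact per category, supplementing — not replacing — home visits).

All magnitudes (demand, staff hours, impact-matrix entries, unit costs) are
synthetic but realistic; they are inputs to exercise the model, not published
calibration data.  The generator is deterministic: the ``seed`` argument is
accepted for interface uniformity and recorded in the run log, but the bundle
content is fixed, so regeneration is byte-identical for any seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .acuity import TransitionParameters
from .bundles import ModelBundle, write_tables
from .costs import UnitCostTable
from .quality import DEFAULT_WEIGHTS, DomainWeights, ImpactMatrix
from .service_model import (CareCategory, CommunityStageSpec, Contact,
                            DesignParameterSpec, HospitalStageSpec,
                            ServiceOption)

logger = logging.getLogger(__name__)

STAY_REDUCTION = 0.20          # option B: −20% length of stay
WARD_STAFF_REDUCTION = 0.10    # option B: −10% regular ward staffing
EXTRA_FEEDING_HOURS = 1.0      # option B: more dedicated feeding/parenting time
CLINIC_CONTACT = Contact("clinic", "maternity_care_assistant", 30.0, 0.0)
HOME_VISIT = Contact("home_visit", "midwife", 40.0, 20.0)
PHONE_CALL = Contact("phone", "midwife", 15.0, 0.0)

_CATEGORY_ROWS = [
    # id, description, annual births, stay h, midwife h, MCA h, feeding h, home visits
    ("0a", "Routine care plus parenting support for healthy mother and baby "
           "but lacking parenting/feeding skill or confidence.",
     2000, 24.0, 2.0, 1.5, 0.5, 2),
    ("0b", "Routine care plus parenting support for healthy mother and baby "
           "but lacking parenting/feeding skill or confidence.",
     1600, 36.0, 3.0, 2.0, 0.5, 2),
    ("1", "Additional care for mother and/or baby with some medical, mental "
          "health and/or social needs.",
     1200, 48.0, 5.0, 3.0, 0.5, 3),
    ("2&3", "Additional or intensive care with liaison with other services to "
            "meet complex or serious health or social needs.",
     400, 72.0, 9.0, 5.0, 1.0, 4),
]

_PARAMETERS = [
    DesignParameterSpec("stay_hours", "Postnatal ward length of stay", "hours",
                        72.0, "hospital", "length_of_stay"),
    DesignParameterSpec("ward_staff_hours", "Regular ward staff hours per case",
                        "staff-hours", 16.0, "hospital", "staff_hours_total"),
    DesignParameterSpec("feeding_support_hours",
                        "Dedicated feeding & parenting support on the ward",
                        "hours", 3.0, "hospital",
                        "dedicated_feeding_parenting_hours"),
    DesignParameterSpec("home_visits", "Community home visits", "visits",
                        6.0, "community", "contact_count:home_visit"),
    DesignParameterSpec("clinic_contacts",
                        "Feeding & parenting clinic attendances", "visits",
                        2.0, "community", "contact_count:clinic"),
]

# Qualitative shape: ward time and stay mainly protect safety; feeding support
# and clinics drive effectiveness and timeliness; home visits carry equity and
# person-centredness (and can offset the safety cost of earlier discharge).
_IMPACT = {
    "stay_hours":            {"safe": 3.0, "effective": 1.0, "timely": 0.0,
                              "equitable": 0.0, "person_centred": 0.5},
    "ward_staff_hours":      {"safe": 4.0, "effective": 3.0, "timely": 1.0,
                              "equitable": 0.5, "person_centred": 1.0},
    "feeding_support_hours": {"safe": 1.0, "effective": 3.0, "timely": 2.0,
                              "equitable": 0.5, "person_centred": 2.0},
    "home_visits":           {"safe": 3.0, "effective": 3.0, "timely": 1.0,
                              "equitable": 3.0, "person_centred": 3.0},
    "clinic_contacts":       {"safe": 1.0, "effective": 2.0, "timely": 2.0,
                              "equitable": 1.0, "person_centred": 1.5},
}

_UNIT_COSTS = UnitCostTable(
    staff_rate_by_grade={"midwife": 44.0, "maternity_care_assistant": 24.0},
    bed_day_rate=400.0,
    clinic_overhead_per_contact=6.0,
    feeding_support_grade="maternity_care_assistant",
)

# Gentle downward drift of acuity while on the ward; the lowest band cannot fall.
_ACUITY = TransitionParameters(
    order=("0a", "0b", "1", "2&3"),
    decay_rate_per_hour={"0a": 0.0, "0b": 0.010, "1": 0.015, "2&3": 0.020},
)


def build_option_a() -> ServiceOption:
    hospital, community = {}, {}
    for cid, _desc, _births, stay, mw, mca, feed, visits in _CATEGORY_ROWS:
        hospital[cid] = HospitalStageSpec(
            length_of_stay_hours=stay,
            staff_hours_by_grade={"midwife": mw, "maternity_care_assistant": mca},
            dedicated_feeding_parenting_hours=feed,
        )
        community[cid] = CommunityStageSpec(
            contacts=tuple([HOME_VISIT] * visits + [PHONE_CALL]))
    return ServiceOption("A", hospital, community)


def build_option_b(option_a: ServiceOption | None = None) -> ServiceOption:
    """Derive option B from option A by the four-item redesign package."""
    a = option_a or build_option_a()
    hospital, community = {}, {}
    for cid in sorted(a.category_ids()):
        h = a.hospital[cid]
        hospital[cid] = HospitalStageSpec(
            length_of_stay_hours=h.length_of_stay_hours * (1 - STAY_REDUCTION),
            staff_hours_by_grade={g: v * (1 - WARD_STAFF_REDUCTION)
                                  for g, v in h.staff_hours_by_grade.items()},
            dedicated_feeding_parenting_hours=(
                h.dedicated_feeding_parenting_hours + EXTRA_FEEDING_HOURS),
        )
        extra_visits = 2 if cid == "2&3" else 1
        community[cid] = CommunityStageSpec(contacts=(
            a.community[cid].contacts
            + (HOME_VISIT,) * extra_visits
            + (CLINIC_CONTACT,)))
    return ServiceOption("B", hospital, community)


def build_fixture_bundle() -> ModelBundle:
    """The demonstration bundle as in-memory objects (no files touched)."""
    categories = tuple(CareCategory(cid, desc, float(births))
                       for cid, desc, births, *_ in _CATEGORY_ROWS)
    option_a = build_option_a()
    return ModelBundle(
        categories=categories,
        specs=tuple(_PARAMETERS),
        matrix=ImpactMatrix.from_dict(_IMPACT),
        weights=DomainWeights(DEFAULT_WEIGHTS),
        unit_costs=_UNIT_COSTS,
        options={"A": option_a, "B": build_option_b(option_a)},
        transition=_ACUITY,
        source="<fixture>",
    )


def generate_fixture(output_dir: str | Path, seed: int = 0) -> Path:
    """Write the demonstration bundle to ``output_dir`` and return the path."""
    logger.info("generating fixture bundle (seed=%d) in %s", seed, output_dir)
    root = Path(output_dir)
    write_tables(build_fixture_bundle(), root)
    return root
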