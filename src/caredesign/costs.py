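"""Per-case and annual costing of hospital and community postnatal care.

Hospital costs are split into two components, reported separately: the staff
cost (ward staff hours plus dedicated feeding-and-parenting support hours, all
priced per grade) and the bed cost (length of stay converted to bed-days and
priced at a bed-day rate covering the bed and its associated infrastructure).
The split matters because quality depends far more on staff-hours than on the
bare length of stay, so a redesign can trade bed-days for staff time.

Community costs price each contact's duration plus any staff travel time at
the visiting grade's hourly rate; clinic contacts add a per-contact overhead.
Phone contacts are priced on duration alone (they carry zero travel by
construction).  Currency is abstract — fixtures use round illustrative rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ConfigurationError
from .service_model import (CareCategory, CommunityStageSpec, HospitalStageSpec,
                            ServiceOption)

#: Grade used to price dedicated feeding/parenting support hours by default.
DEFAULT_FEEDING_SUPPORT_GRADE = "maternity_care_assistant"


@dataclass(frozen=True)
class UnitCostTable:
    staff_rate_by_grade: Mapping[str, float]  # currency per hour
    bed_day_rate: float                       # currency per bed-day
    clinic_overhead_per_contact: float = 0.0
    feeding_support_grade: str = DEFAULT_FEEDING_SUPPORT_GRADE

    def rate(self, grade: str) -> float:
        try:
            return float(self.staff_rate_by_grade[grade])
        except KeyError:
            raise ConfigurationError(f"no unit cost rate for staff grade {grade!r}")

    def violations(self) -> list[str]:
        out = []
        for grade, r in self.staff_rate_by_grade.items():
            if not (r >= 0):
                out.append(f"staff rate for {grade!r} must be >= 0, got {r}")
        if not (self.bed_day_rate >= 0):
            out.append(f"bed_day_rate must be >= 0, got {self.bed_day_rate}")
        if not (self.clinic_overhead_per_contact >= 0):
            out.append(f"clinic_overhead_per_contact must be >= 0, "
                       f"got {self.clinic_overhead_per_contact}")
        return out


@dataclass(frozen=True)
class CategoryCost:
    """Per-case cost components and the annual total for one care category."""

    hospital_staff_per_case: float
    hospital_bed_per_case: float
    community_per_case: float
    annual_births: float

    @property
    def per_case_total(self) -> float:
        return (self.hospital_staff_per_case + self.hospital_bed_per_case
                + self.community_per_case)

    @property
    def annual_total(self) -> float:
        return self.annual_births * self.per_case_total


@dataclass(frozen=True)
class CostBreakdown:
    option_name: str
    per_category: Mapping[str, CategoryCost] = field(default_factory=dict)

    @property
    def service_annual_total(self) -> float:
        return sum(c.annual_total for c in self.per_category.values())

    def to_frame(self):
        import pandas as pd
        rows = {
            cat: {
                "hospital_staff_per_case": c.hospital_staff_per_case,
                "hospital_bed_per_case": c.hospital_bed_per_case,
                "community_per_case": c.community_per_case,
                "per_case_total": c.per_case_total,
                "annual_births": c.annual_births,
                "annual_total": c.annual_total,
            }
            for cat, c in self.per_category.items()
        }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "category"
        return df


def hospital_cost_per_case(stage: HospitalStageSpec,
                           costs: UnitCostTable) -> tuple[float, float]:
    """Return (staff_cost, bed_cost) per case for one category's hospital stage."""
    staff = sum(hours * costs.rate(grade)
                for grade, hours in stage.staff_hours_by_grade.items())
    if stage.dedicated_feeding_parenting_hours:
        staff += (stage.dedicated_feeding_parenting_hours
                  * costs.rate(costs.feeding_support_grade))
    bed = (stage.length_of_stay_hours / 24.0) * costs.bed_day_rate
    return staff, bed


def community_cost_per_case(stage: CommunityStageSpec,
                            costs: UnitCostTable) -> float:
    """Cost of the community contact schedule for one case."""
    total = 0.0
    for c in stage.contacts:
        total += (c.duration_minutes + c.travel_minutes) / 60.0 * costs.rate(c.grade)
        if c.kind == "clinic":
            total += costs.clinic_overhead_per_contact
    return total


def annual_cost(option: ServiceOption,
                categories: Iterable[CareCategory],
                costs: UnitCostTable,
                community_births: Mapping[str, float] | None = None,
                ) -> CostBreakdown:
    """Per-category and service-level annual cost of a service option.

    ``community_births`` optionally overrides the demand used for the
    community stage of each category (e.g. the acuity mix at discharge after a
    shortened hospital stay, scaled to total births); hospital-stage demand is
    always the categories' admission demand.
    """
    per_category: dict[str, CategoryCost] = {}
    for cat in categories:
        hosp = option.hospital.get(cat.id, HospitalStageSpec(0.0))
        comm = option.community.get(cat.id, CommunityStageSpec())
        staff, bed = hospital_cost_per_case(hosp, costs)
        community = community_cost_per_case(comm, costs)
        if community_births is not None:
            n_comm = community_births.get(cat.id, 0.0)
            n_hosp = cat.annual_births
            # mixed demand: report an effective per-case community cost so the
            # additivity invariant (annual = births * per-case sum) still holds
            community_eff = (community * n_comm / n_hosp) if n_hosp > 0 else 0.0
        else:
            community_eff = community
        per_category[cat.id] = CategoryCost(
            hospital_staff_per_case=staff,
            hospital_bed_per_case=bed,
            community_per_case=community_eff,
            annual_births=cat.annual_births,
        )
    return CostBreakdown(option.name, per_category)
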