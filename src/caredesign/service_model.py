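"""Domain types for care categories, design parameters and service options.

A *service option* describes one way of running a postnatal service: for every
care category (acuity band of mother/baby dyads) it specifies the hospital stage
(length of stay, ward staff hours by grade, dedicated feeding-and-parenting
support hours) and the community stage (a list of staff contacts — home visits,
clinic attendances, phone calls). *Design parameters* are the controllable
levers of the service; each carries a maximum beneficial value z_i beyond which
no further quality benefit is assumed, and a derivation rule that maps the
structured stage specification onto the flat parameter value x_i consumed by
the quality-scoring equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .errors import ConfigurationError

CONTACT_KINDS = ("home_visit", "clinic", "phone")
SETTINGS = ("hospital", "community")


@dataclass(frozen=True)
class CareCategory:
    """A broad category of care need (acuity band), e.g. '0a' or '2&3'."""

    id: str
    description: str
    annual_births: float

    def violations(self) -> list[str]:
        out = []
        if not self.id:
            out.append("category id must be non-empty")
        if not (self.annual_births >= 0):
            out.append(f"category {self.id!r}: annual_births must be >= 0, "
                       f"got {self.annual_births}")
        return out


@dataclass(frozen=True)
class DesignParameterSpec:
    """A controllable service lever with its maximum beneficial value z_i.

    ``derivation`` names the rule that extracts the parameter's value x_i from
    a service option's stage specifications; see :func:`derive_parameter_values`.
    """

    id: str
    label: str
    unit: str
    max_beneficial_value: float
    setting: str  # "hospital" | "community"
    derivation: str

    def violations(self) -> list[str]:
        out = []
        if not (self.max_beneficial_value > 0):
            out.append(f"parameter {self.id!r}: max_beneficial_value must be > 0, "
                       f"got {self.max_beneficial_value}")
        if self.setting not in SETTINGS:
            out.append(f"parameter {self.id!r}: setting must be one of {SETTINGS}, "
                       f"got {self.setting!r}")
        return out


@dataclass(frozen=True)
class Contact:
    """One community-stage staff contact.

    Clinic and phone contacts carry no staff travel time.
    """

    kind: str  # "home_visit" | "clinic" | "phone"
    grade: str
    duration_minutes: float
    travel_minutes: float = 0.0

    def violations(self, where: str = "") -> list[str]:
        out = []
        loc = f"{where}: " if where else ""
        if self.kind not in CONTACT_KINDS:
            out.append(f"{loc}contact kind must be one of {CONTACT_KINDS}, "
                       f"got {self.kind!r}")
        if not (self.duration_minutes >= 0):
            out.append(f"{loc}duration_minutes must be >= 0, got {self.duration_minutes}")
        if not (self.travel_minutes >= 0):
            out.append(f"{loc}travel_minutes must be >= 0, got {self.travel_minutes}")
        if self.kind in ("clinic", "phone") and self.travel_minutes:
            out.append(f"{loc}{self.kind} contact must have zero travel_minutes, "
                       f"got {self.travel_minutes}")
        return out


@dataclass(frozen=True)
class HospitalStageSpec:
    """Hospital postnatal stage for one care category."""

    length_of_stay_hours: float
    staff_hours_by_grade: Mapping[str, float] = field(default_factory=dict)
    dedicated_feeding_parenting_hours: float = 0.0

    def violations(self, where: str = "") -> list[str]:
        out = []
        loc = f"{where}: " if where else ""
        if not (self.length_of_stay_hours >= 0):
            out.append(f"{loc}length_of_stay_hours must be >= 0, "
                       f"got {self.length_of_stay_hours}")
        for grade, hours in self.staff_hours_by_grade.items():
            if not (hours >= 0):
                out.append(f"{loc}staff_hours_by_grade[{grade!r}] must be >= 0, "
                           f"got {hours}")
        if not (self.dedicated_feeding_parenting_hours >= 0):
            out.append(f"{loc}dedicated_feeding_parenting_hours must be >= 0, "
                       f"got {self.dedicated_feeding_parenting_hours}")
        return out


@dataclass(frozen=True)
class CommunityStageSpec:
    """Community postnatal stage for one care category: the contact schedule."""

    contacts: tuple[Contact, ...] = ()

    def violations(self, where: str = "") -> list[str]:
        out = []
        for k, c in enumerate(self.contacts):
            out.extend(c.violations(f"{where}.contacts[{k}]" if where else f"contacts[{k}]"))
        return out


@dataclass(frozen=True)
class ServiceOption:
    """A complete service specification: one stage pair per care category."""

    name: str
    hospital: Mapping[str, HospitalStageSpec]
    community: Mapping[str, CommunityStageSpec]

    def category_ids(self) -> set[str]:
        return set(self.hospital) | set(self.community)


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of validating a service option; empty iff the option is well formed."""

    violations: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy when valid
        return self.ok


# ---------------------------------------------------------------------------
# Derivation of parameter values x_i from stage specifications
# ---------------------------------------------------------------------------

def _derive_one(spec: DesignParameterSpec,
                hospital: HospitalStageSpec,
                community: CommunityStageSpec) -> float:
    rule, _, arg = spec.derivation.partition(":")
    if rule == "length_of_stay":
        return float(hospital.length_of_stay_hours)
    if rule == "staff_hours_total":
        return float(sum(hospital.staff_hours_by_grade.values()))
    if rule == "staff_hours":
        if not arg:
            raise ConfigurationError(
                f"parameter {spec.id!r}: rule 'staff_hours' needs a grade argument")
        return float(hospital.staff_hours_by_grade.get(arg, 0.0))
    if rule == "dedicated_feeding_parenting_hours":
        return float(hospital.dedicated_feeding_parenting_hours)
    if rule == "contact_count":
        return float(sum(1 for c in community.contacts
                         if not arg or c.kind == arg))
    if rule == "contact_minutes":
        return float(sum(c.duration_minutes for c in community.contacts
                         if not arg or c.kind == arg))
    raise ConfigurationError(
        f"parameter {spec.id!r}: unknown derivation rule {spec.derivation!r}")


def derive_parameter_values(option: ServiceOption,
                            specs: Iterable[DesignParameterSpec],
                            ) -> dict[str, dict[str, float]]:
    """Map a service option onto the flat parameter vectors x_i, per category.

    Returns ``{category_id: {parameter_id: x_i}}``.  Pure and deterministic:
    the result depends only on the option and the specs.

    Raises
    ------
    ConfigurationError
        If a spec carries an unknown derivation rule.
    """
    specs = list(specs)
    out: dict[str, dict[str, float]] = {}
    for cat in sorted(option.category_ids()):
        hosp = option.hospital.get(cat, HospitalStageSpec(0.0))
        comm = option.community.get(cat, CommunityStageSpec())
        out[cat] = {s.id: _derive_one(s, hosp, comm) for s in specs}
    return out


def apply_parameter_value(option: ServiceOption, spec: DesignParameterSpec,
                          category_id: str, value: float) -> ServiceOption:
    """Return a copy of ``option`` whose derived x for ``spec`` equals ``value``.

    Inverse of :func:`derive_parameter_values` for one (category, parameter)
    cell, used by one-way sensitivity sweeps so that both quality and cost are
    recomputed from a genuinely modified option.  Count-type rules require a
    non-negative integer ``value``; new contacts clone the last existing contact
    of the same kind (default: a 40-minute midwife home visit with 20 minutes
    of travel, or a 30-minute midwife clinic/phone contact).
    """
    if value < 0:
        raise ConfigurationError(
            f"parameter {spec.id!r}: cannot set negative value {value}")
    hosp = option.hospital[category_id]
    comm = option.community[category_id]
    rule, _, arg = spec.derivation.partition(":")

    if rule == "length_of_stay":
        hosp = replace(hosp, length_of_stay_hours=float(value))
    elif rule == "staff_hours_total":
        total = sum(hosp.staff_hours_by_grade.values())
        if total == 0 and value > 0:
            raise ConfigurationError(
                f"parameter {spec.id!r}: cannot scale zero staff hours up "
                f"(no grade mix to preserve)")
        scale = 0.0 if total == 0 else float(value) / total
        hosp = replace(hosp, staff_hours_by_grade={
            g: h * scale for g, h in hosp.staff_hours_by_grade.items()})
    elif rule == "staff_hours":
        mix = dict(hosp.staff_hours_by_grade)
        mix[arg] = float(value)
        hosp = replace(hosp, staff_hours_by_grade=mix)
    elif rule == "dedicated_feeding_parenting_hours":
        hosp = replace(hosp, dedicated_feeding_parenting_hours=float(value))
    elif rule == "contact_count":
        if abs(value - round(value)) > 1e-9:
            raise ConfigurationError(
                f"parameter {spec.id!r}: contact counts must be integers, got {value}")
        n = int(round(value))
        kept = [c for c in comm.contacts if arg and c.kind != arg]
        pool = [c for c in comm.contacts if not arg or c.kind == arg]
        if n <= len(pool):
            pool = pool[:n]
        else:
            template = pool[-1] if pool else _default_contact(arg or "home_visit")
            pool = pool + [template] * (n - len(pool))
        comm = CommunityStageSpec(contacts=tuple(kept + pool))
    elif rule == "contact_minutes":
        current = sum(c.duration_minutes for c in comm.contacts
                      if not arg or c.kind == arg)
        if current == 0 and value > 0:
            raise ConfigurationError(
                f"parameter {spec.id!r}: cannot scale zero contact minutes up")
        scale = 0.0 if current == 0 else float(value) / current
        comm = CommunityStageSpec(contacts=tuple(
            replace(c, duration_minutes=c.duration_minutes * scale)
            if (not arg or c.kind == arg) else c
            for c in comm.contacts))
    else:
        raise ConfigurationError(
            f"parameter {spec.id!r}: unknown derivation rule {spec.derivation!r}")

    hospital = dict(option.hospital)
    community = dict(option.community)
    hospital[category_id] = hosp
    community[category_id] = comm
    return ServiceOption(option.name, hospital, community)


def _default_contact(kind: str) -> Contact:
    if kind == "home_visit":
        return Contact("home_visit", "midwife", 40.0, 20.0)
    return Contact(kind, "midwife", 30.0, 0.0)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_service(option: ServiceOption,
                     categories: Iterable[CareCategory]) -> ValidationReport:
    """Check a service option against the declared care categories.

    Violations are returned as data (a report), never raised: the caller
    decides whether an invalid option is fatal.
    """
    categories = list(categories)
    violations: list[str] = []

    ids = [c.id for c in categories]
    dupes = {i for i in ids if ids.count(i) > 1}
    for d in sorted(dupes):
        violations.append(f"duplicate care category id {d!r}")
    for cat in categories:
        violations.extend(cat.violations())

    declared = set(ids)
    covered = option.category_ids()
    for missing in sorted(declared - covered):
        violations.append(f"option {option.name!r}: missing category {missing!r}")
    for extra in sorted(covered - declared):
        violations.append(f"option {option.name!r}: undeclared category {extra!r}")
    for cat in sorted(declared & covered):
        if cat not in option.hospital:
            violations.append(f"option {option.name!r}: category {cat!r} has no "
                              f"hospital stage")
        else:
            violations.extend(option.hospital[cat].violations(
                f"option {option.name!r} category {cat!r} hospital"))
        if cat not in option.community:
            violations.append(f"option {option.name!r}: category {cat!r} has no "
                              f"community stage")
        else:
            violations.extend(option.community[cat].violations(
                f"option {option.name!r} category {cat!r} community"))

    # NaNs never satisfy >= 0 checks above, but guard stay explicitly
    for cat, h in option.hospital.items():
        if isinstance(h.length_of_stay_hours, float) and math.isnan(h.length_of_stay_hours):
            violations.append(f"option {option.name!r} category {cat!r}: "
                              f"length_of_stay_hours is NaN")

    return ValidationReport(tuple(violations))


def validate_parameter_specs(specs: Iterable[DesignParameterSpec]) -> list[str]:
    """Collect violations across a set of parameter specs (unique ids, z_i > 0)."""
    specs = list(specs)
    out: list[str] = []
    ids = [s.id for s in specs]
    for d in sorted({i for i in ids if ids.count(i) > 1}):
        out.append(f"duplicate design parameter id {d!r}")
    for s in specs:
        out.extend(s.violations())
    return out
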