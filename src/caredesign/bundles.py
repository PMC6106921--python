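"""Reading and writing model bundles.

A *bundle* is a directory of plain structured-text files that together define
one model: care categories, design parameter specs, impact matrix, domain
weights, unit costs, one or more service options and (optionally) acuity
transition parameters.  Everything is delimiter-separated tables or small YAML
documents so workshop participants can inspect and edit inputs directly.

Layout::

    bundle/
      config.yaml          # bed-day rate, clinic overhead, feeding grade,
                           # optional acuity block
      categories.csv       # id, description, annual_births
      parameters.csv       # id, label, unit, max_beneficial_value, setting,
                           # derivation
      impact_matrix.csv    # parameter_id, one column per quality domain
      weights.csv          # domain, weight
      unit_costs.csv       # grade, rate
      options/*.yaml       # one service option per file

Loading cross-validates the whole bundle and reports every failure at once,
not just the first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .acuity import TransitionParameters
from .costs import DEFAULT_FEEDING_SUPPORT_GRADE, UnitCostTable
from .errors import (BundleValidationError, ConfigurationError,
                     ModelSpecificationError)
from .quality import DOMAINS, DomainWeights, ImpactMatrix
from .service_model import (CareCategory, CommunityStageSpec, Contact,
                            DesignParameterSpec, HospitalStageSpec,
                            ServiceOption, derive_parameter_values,
                            validate_parameter_specs, validate_service)


@dataclass(frozen=True)
class ModelBundle:
    """A fully resolved and cross-validated model."""

    categories: tuple[CareCategory, ...]
    specs: tuple[DesignParameterSpec, ...]
    matrix: ImpactMatrix
    weights: DomainWeights
    unit_costs: UnitCostTable
    options: Mapping[str, ServiceOption]
    transition: TransitionParameters | None = None
    source: str = ""

    def option(self, name: str) -> ServiceOption:
        try:
            return self.options[name]
        except KeyError:
            raise ConfigurationError(
                f"bundle has no option {name!r}; available: {sorted(self.options)}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.is_file():
        raise ConfigurationError(f"missing bundle file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV: report file and cause
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing columns {missing}")
    return df


def read_option(path: Path) -> ServiceOption:
    """Read one service option from its YAML file."""
    if not path.is_file():
        raise ConfigurationError(f"missing option file: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict) or "name" not in doc or "categories" not in doc:
        raise ConfigurationError(f"{path}: option file needs 'name' and 'categories'")
    hospital: dict[str, HospitalStageSpec] = {}
    community: dict[str, CommunityStageSpec] = {}
    for cid, stages in doc["categories"].items():
        cid = str(cid)
        h = stages.get("hospital", {})
        hospital[cid] = HospitalStageSpec(
            length_of_stay_hours=float(h.get("length_of_stay_hours", 0.0)),
            staff_hours_by_grade={str(g): float(v) for g, v in
                                  (h.get("staff_hours_by_grade") or {}).items()},
            dedicated_feeding_parenting_hours=float(
                h.get("dedicated_feeding_parenting_hours", 0.0)),
        )
        contacts = []
        for c in (stages.get("community", {}).get("contacts") or []):
            contacts.append(Contact(
                kind=str(c["kind"]), grade=str(c["grade"]),
                duration_minutes=float(c["duration_minutes"]),
                travel_minutes=float(c.get("travel_minutes", 0.0))))
        community[cid] = CommunityStageSpec(contacts=tuple(contacts))
    return ServiceOption(str(doc["name"]), hospital, community)


def write_option(option: ServiceOption, path: Path) -> None:
    """Write a service option as YAML; deterministic (sorted keys, fixed style)."""
    doc = {"name": option.name, "categories": {}}
    for cid in sorted(option.category_ids()):
        h = option.hospital[cid]
        c = option.community[cid]
        doc["categories"][cid] = {
            "hospital": {
                "length_of_stay_hours": float(h.length_of_stay_hours),
                "staff_hours_by_grade": {g: float(v) for g, v in
                                         sorted(h.staff_hours_by_grade.items())},
                "dedicated_feeding_parenting_hours":
                    float(h.dedicated_feeding_parenting_hours),
            },
            "community": {
                "contacts": [
                    {"kind": ct.kind, "grade": ct.grade,
                     "duration_minutes": float(ct.duration_minutes),
                     "travel_minutes": float(ct.travel_minutes)}
                    for ct in c.contacts
                ],
            },
        }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(doc, sort_keys=True, default_flow_style=False))


def load_bundle(bundle_dir: str | Path) -> ModelBundle:
    """Load and cross-validate a bundle directory.

    Raises
    ------
    ConfigurationError
        If a file is missing or cannot be parsed (reported per file).
    BundleValidationError
        If parsing succeeds but validation fails; carries *all* violations.
    """
    root = Path(bundle_dir)
    violations: list[str] = []

    cat_df = _read_csv(root / "categories.csv",
                       ["id", "description", "annual_births"])
    categories = tuple(CareCategory(str(r.id), str(r.description),
                                    float(r.annual_births))
                       for r in cat_df.itertuples())

    par_df = _read_csv(root / "parameters.csv",
                       ["id", "label", "unit", "max_beneficial_value",
                        "setting", "derivation"])
    specs = tuple(DesignParameterSpec(str(r.id), str(r.label), str(r.unit),
                                      float(r.max_beneficial_value),
                                      str(r.setting), str(r.derivation))
                  for r in par_df.itertuples())
    violations.extend(validate_parameter_specs(specs))

    mat_df = _read_csv(root / "impact_matrix.csv", ["parameter_id"])
    mat_df = mat_df.set_index("parameter_id")
    domains = [c for c in mat_df.columns]
    unknown_domains = [d for d in domains if d not in DOMAINS]
    for d in unknown_domains:
        violations.append(f"impact_matrix: unknown quality domain {d!r}")
    matrix = ImpactMatrix(mat_df.astype(float))
    violations.extend(matrix.violations(specs))

    w_df = _read_csv(root / "weights.csv", ["domain", "weight"])
    raw_weights = {str(r.domain): float(r.weight) for r in w_df.itertuples()}
    weights = None
    try:
        weights = DomainWeights(raw_weights)
    except ModelSpecificationError as exc:
        violations.append(f"weights: {exc}")

    uc_df = _read_csv(root / "unit_costs.csv", ["grade", "rate"])
    config_path = root / "config.yaml"
    if not config_path.is_file():
        raise ConfigurationError(f"missing bundle file: {config_path}")
    try:
        config = yaml.safe_load(config_path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {config_path}: {exc}") from exc
    unit_costs = UnitCostTable(
        staff_rate_by_grade={str(r.grade): float(r.rate)
                             for r in uc_df.itertuples()},
        bed_day_rate=float(config.get("bed_day_rate", 0.0)),
        clinic_overhead_per_contact=float(
            config.get("clinic_overhead_per_contact", 0.0)),
        feeding_support_grade=str(config.get("feeding_support_grade",
                                             DEFAULT_FEEDING_SUPPORT_GRADE)),
    )
    violations.extend(unit_costs.violations())

    options: dict[str, ServiceOption] = {}
    opt_dir = root / "options"
    for path in sorted(opt_dir.glob("*.yaml")) if opt_dir.is_dir() else []:
        opt = read_option(path)
        if opt.name in options:
            violations.append(f"duplicate option name {opt.name!r} ({path.name})")
        options[opt.name] = opt
    if not options:
        violations.append(f"no option files found under {opt_dir}")

    for opt in options.values():
        violations.extend(validate_service(opt, categories).violations)
        try:
            derive_parameter_values(opt, specs)
        except ConfigurationError as exc:
            violations.append(str(exc))
        grades = set(unit_costs.staff_rate_by_grade)
        for cid, h in opt.hospital.items():
            for g in h.staff_hours_by_grade:
                if g not in grades:
                    violations.append(f"option {opt.name!r} category {cid!r}: "
                                      f"no unit cost for grade {g!r}")
            if (h.dedicated_feeding_parenting_hours
                    and unit_costs.feeding_support_grade not in grades):
                violations.append(f"no unit cost for feeding support grade "
                                  f"{unit_costs.feeding_support_grade!r}")
        for cid, c in opt.community.items():
            for ct in c.contacts:
                if ct.grade not in grades:
                    violations.append(f"option {opt.name!r} category {cid!r}: "
                                      f"no unit cost for grade {ct.grade!r}")

    transition = None
    acuity_cfg = config.get("acuity")
    if acuity_cfg:
        try:
            transition = TransitionParameters(
                order=tuple(str(c) for c in acuity_cfg["order"]),
                decay_rate_per_hour={str(c): float(v) for c, v in
                                     acuity_cfg["decay_rate_per_hour"].items()})
        except (KeyError, TypeError, ModelSpecificationError) as exc:
            violations.append(f"acuity: {exc}")

    if violations:
        raise BundleValidationError(sorted(set(violations)))
    return ModelBundle(categories, specs, matrix, weights, unit_costs,
                       options, transition, source=str(root))


def write_tables(bundle: ModelBundle, root: Path) -> None:
    """Write the tabular parts of a bundle (used by the fixture generator)."""
    root.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"id": c.id, "description": c.description,
          "annual_births": c.annual_births} for c in bundle.categories]
    ).to_csv(root / "categories.csv", index=False)
    pd.DataFrame(
        [{"id": s.id, "label": s.label, "unit": s.unit,
          "max_beneficial_value": s.max_beneficial_value,
          "setting": s.setting, "derivation": s.derivation}
         for s in bundle.specs]
    ).to_csv(root / "parameters.csv", index=False)
    mat = bundle.matrix.table.copy()
    mat.index.name = "parameter_id"
    mat.to_csv(root / "impact_matrix.csv")
    pd.DataFrame(
        [{"domain": d, "weight": w} for d, w in bundle.weights.items()]
    ).to_csv(root / "weights.csv", index=False)
    pd.DataFrame(
        sorted(({"grade": g, "rate": r} for g, r in
                bundle.unit_costs.staff_rate_by_grade.items()),
               key=lambda d: d["grade"])
    ).to_csv(root / "unit_costs.csv", index=False)
    config = {
        "bed_day_rate": float(bundle.unit_costs.bed_day_rate),
        "clinic_overhead_per_contact":
            float(bundle.unit_costs.clinic_overhead_per_contact),
        "feeding_support_grade": bundle.unit_costs.feeding_support_grade,
    }
    if bundle.transition is not None:
        config["acuity"] = {
            "order": list(bundle.transition.order),
            "decay_rate_per_hour":
                {c: float(v) for c, v in
                 bundle.transition.decay_rate_per_hour.items()},
        }
    (root / "config.yaml").write_text(
        yaml.safe_dump(config, sort_keys=True, default_flow_style=False))
    for key, opt in sorted(bundle.options.items()):
        write_option(opt, root / "options" / f"option_{key.lower()}.yaml")
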