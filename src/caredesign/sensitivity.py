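"""Deterministic sensitivity analysis.

Two instruments:

* :func:`weight_sweep` — perturb selected quality-domain weights by fixed
  deltas (default ±0.1 and ±0.2), renormalizing the remaining weights
  proportionally, and recompute the option-B-minus-option-A aggregate quality
  delta for every category under each perturbed weight vector.  A category's
  conclusion is flagged robust when the sign of its aggregate delta never
  changes across the whole sweep.
* :func:`parameter_sweep` — vary one design parameter over a grid of values,
  fully recomputing domain scores, the aggregate and the annual cost at each
  grid point (no state is carried between rows).

Monte Carlo uncertainty propagation is deliberately out of scope; the
deterministic sweeps are the extension point where it would plug in.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .comparison import compare_options
from .costs import UnitCostTable, annual_cost
from .errors import ConfigurationError
from .quality import (DomainWeights, ImpactMatrix, aggregate_score,
                      renormalize_weights, score_profile)
from .service_model import (CareCategory, DesignParameterSpec, ServiceOption,
                            apply_parameter_value, derive_parameter_values)

logger = logging.getLogger(__name__)

DEFAULT_SWEEP_DOMAINS = ("safe", "effective", "person_centred")
DEFAULT_SWEEP_DELTAS = (-0.2, -0.1, 0.1, 0.2)


@dataclass(frozen=True)
class WeightSweepRow:
    domain: str
    delta: float                      # applied to the domain's weight
    weights: DomainWeights            # full renormalized vector
    aggregate_deltas: Mapping[str, float]  # category -> quality delta (B - A)


@dataclass(frozen=True)
class WeightSweepResult:
    baseline_deltas: Mapping[str, float]  # category -> delta at original weights
    rows: tuple[WeightSweepRow, ...]
    robustness: Mapping[str, bool]        # category -> sign never flips

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec = {"domain": row.domain, "delta": row.delta}
            rec.update({f"w_{d}": w for d, w in row.weights.items()})
            rec.update({f"d_aggregate[{c}]": v
                        for c, v in row.aggregate_deltas.items()})
            records.append(rec)
        return pd.DataFrame.from_records(records)


def weight_sweep(option_a: ServiceOption,
                 option_b: ServiceOption,
                 specs: Iterable[DesignParameterSpec],
                 matrix: ImpactMatrix,
                 weights: DomainWeights,
                 costs: UnitCostTable,
                 categories: Iterable[CareCategory],
                 domains: Sequence[str] = DEFAULT_SWEEP_DOMAINS,
                 deltas: Sequence[float] = DEFAULT_SWEEP_DELTAS,
                 cap: bool = True) -> WeightSweepResult:
    """Weight-perturbation sweep over the B-minus-A aggregate quality deltas.

    Perturbations that would push a weight outside [0, 1] are skipped with a
    logged warning rather than failing the whole sweep.
    """
    specs = list(specs)
    categories = list(categories)
    base = compare_options(option_a, option_b, specs, matrix, weights, costs,
                           categories, cap=cap)
    baseline = {c: cc.aggregate_delta for c, cc in base.per_category.items()}

    # domain scores are weight-independent; only the aggregation changes
    rows: list[WeightSweepRow] = []
    for dom in domains:
        for delta in deltas:
            target = weights[dom] + delta
            if not (0.0 <= target <= 1.0):
                logger.warning("skipping perturbation %s%+g: weight %g outside [0, 1]",
                               dom, delta, target)
                continue
            w = renormalize_weights(weights, dom, target)
            agg = {
                cid: (aggregate_score(base.profile_b.domain_scores[cid], w)
                      - aggregate_score(base.profile_a.domain_scores[cid], w))
                for cid in baseline
            }
            rows.append(WeightSweepRow(dom, delta, w, agg))

    robustness = {}
    for cid, base_delta in baseline.items():
        signs = {math.copysign(1.0, v) if v != 0 else 0.0
                 for v in [base_delta] + [r.aggregate_deltas[cid] for r in rows]}
        robustness[cid] = len(signs - {0.0}) <= 1
    return WeightSweepResult(baseline, tuple(rows), robustness)


def parameter_sweep(option: ServiceOption,
                    parameter_id: str,
                    grid: Sequence[float],
                    specs: Iterable[DesignParameterSpec],
                    matrix: ImpactMatrix,
                    weights: DomainWeights,
                    costs: UnitCostTable,
                    categories: Iterable[CareCategory],
                    category_id: str | None = None,
                    cap: bool = True) -> pd.DataFrame:
    """One-way sweep of a design parameter over a grid of values.

    Each grid value is written back into the option (stay hours set directly,
    contact counts by cloning/trimming contacts, minutes and staff hours by
    proportional scaling) and the whole pipeline — scores, aggregate, annual
    cost — is recomputed from that modified option.  When ``category_id`` is
    None the value is applied to every category.
    """
    specs = list(specs)
    categories = list(categories)
    by_id = {s.id: s for s in specs}
    if parameter_id not in by_id:
        raise ConfigurationError(f"unknown design parameter {parameter_id!r}")
    spec = by_id[parameter_id]
    target_cats = [category_id] if category_id else sorted(option.category_ids())

    records = []
    for value in grid:
        if not (value >= 0):
            raise ConfigurationError(
                f"grid values must be >= 0, got {value}")
        modified = option
        for cid in target_cats:
            modified = apply_parameter_value(modified, spec, cid, value)
        x = derive_parameter_values(modified, specs)
        profile = score_profile(x, specs, matrix, weights, modified.name, cap=cap)
        cost = annual_cost(modified, categories, costs)
        for cid in (target_cats if category_id else sorted(x)):
            rec = {"value": float(value), "category": cid}
            rec.update({f"s_{d}": profile.domain_scores[cid][d]
                        for d in matrix.domain_ids})
            rec["aggregate"] = profile.aggregates[cid]
            rec["annual_cost"] = cost.per_category[cid].annual_total
            records.append(rec)
    return pd.DataFrame.from_records(records)
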