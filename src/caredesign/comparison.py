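"""Option-vs-option assessment and equity-impact-plane classification.

A redesign (option B) is compared with the current service (option A) by
recomputing quality profiles and cost breakdowns for both and differencing:
per-category domain-score deltas, aggregate quality deltas, per-case and
annual cost deltas, a service-level percentage saving, and for each category a
quadrant of the health equity impact plane.  "Win-win" means quality strictly
up and cost strictly down; a zero delta on either axis is classified neutral
(the boundary is not forced into a quadrant).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .costs import CostBreakdown, UnitCostTable, annual_cost
from .errors import ModelSpecificationError
from .quality import (DomainWeights, ImpactMatrix, QualityProfile,
                      score_profile)
from .service_model import (CareCategory, DesignParameterSpec, ServiceOption,
                            derive_parameter_values)


class EquityQuadrant(Enum):
    WIN_WIN = "win_win"      # quality up, cost down
    WIN_LOSE = "win_lose"    # quality up, cost up
    LOSE_WIN = "lose_win"    # quality down, cost down
    LOSE_LOSE = "lose_lose"  # quality down, cost up
    NEUTRAL = "neutral"      # on either axis


def classify_equity(quality_delta: float, cost_delta: float) -> EquityQuadrant:
    """Place a (quality change, cost change) pair in the equity impact plane."""
    for v in (quality_delta, cost_delta):
        if v != v or v in (float("inf"), float("-inf")):
            raise ModelSpecificationError(f"non-finite delta {v!r}")
    if quality_delta == 0 or cost_delta == 0:
        return EquityQuadrant.NEUTRAL
    if quality_delta > 0:
        return EquityQuadrant.WIN_WIN if cost_delta < 0 else EquityQuadrant.WIN_LOSE
    return EquityQuadrant.LOSE_WIN if cost_delta < 0 else EquityQuadrant.LOSE_LOSE


@dataclass(frozen=True)
class CategoryComparison:
    domain_deltas: Mapping[str, float]  # domain -> s_j(B) - s_j(A)
    aggregate_delta: float
    per_case_cost_delta: float
    annual_cost_delta: float
    quadrant: EquityQuadrant


@dataclass(frozen=True)
class OptionComparison:
    option_a: str
    option_b: str
    per_category: Mapping[str, CategoryComparison]
    profile_a: QualityProfile
    profile_b: QualityProfile
    costs_a: CostBreakdown
    costs_b: CostBreakdown

    @property
    def annual_cost_delta(self) -> float:
        return self.costs_b.service_annual_total - self.costs_a.service_annual_total

    @property
    def percentage_saving(self) -> float:
        """100 * (cost_A - cost_B) / cost_A; positive when B is cheaper."""
        total_a = self.costs_a.service_annual_total
        if total_a <= 0:
            raise ModelSpecificationError(
                "percentage saving undefined for non-positive baseline cost")
        return 100.0 * (total_a - self.costs_b.service_annual_total) / total_a

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for cat, cc in self.per_category.items():
            row = {f"d_{dom}": delta for dom, delta in cc.domain_deltas.items()}
            row["d_aggregate"] = cc.aggregate_delta
            row["d_cost_per_case"] = cc.per_case_cost_delta
            row["d_cost_annual"] = cc.annual_cost_delta
            row["quadrant"] = cc.quadrant.value
            rows[cat] = row
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "category"
        return df


def compare_options(option_a: ServiceOption,
                    option_b: ServiceOption,
                    specs: Iterable[DesignParameterSpec],
                    matrix: ImpactMatrix,
                    weights: DomainWeights,
                    costs: UnitCostTable,
                    categories: Iterable[CareCategory],
                    cap: bool = True) -> OptionComparison:
    """Full A-vs-B comparison: quality deltas, cost deltas, equity quadrants.

    Everything is recomputed from the two options — deltas are never cached —
    so ``compare_options(A, B)`` is the exact negation of
    ``compare_options(B, A)``.
    """
    specs = list(specs)
    categories = list(categories)
    declared = {c.id for c in categories}
    if option_a.category_ids() != declared or option_b.category_ids() != declared:
        raise ModelSpecificationError(
            f"options must cover exactly the declared categories {sorted(declared)}; "
            f"got {sorted(option_a.category_ids())} and "
            f"{sorted(option_b.category_ids())}")

    xa = derive_parameter_values(option_a, specs)
    xb = derive_parameter_values(option_b, specs)
    prof_a = score_profile(xa, specs, matrix, weights, option_a.name, cap=cap)
    prof_b = score_profile(xb, specs, matrix, weights, option_b.name, cap=cap)
    cost_a = annual_cost(option_a, categories, costs)
    cost_b = annual_cost(option_b, categories, costs)

    per_category: dict[str, CategoryComparison] = {}
    for cat in categories:
        cid = cat.id
        dd = {dom: prof_b.domain_scores[cid][dom] - prof_a.domain_scores[cid][dom]
              for dom in matrix.domain_ids}
        agg_delta = prof_b.aggregates[cid] - prof_a.aggregates[cid]
        ca, cb = cost_a.per_category[cid], cost_b.per_category[cid]
        per_case_delta = cb.per_case_total - ca.per_case_total
        per_category[cid] = CategoryComparison(
            domain_deltas=dd,
            aggregate_delta=agg_delta,
            per_case_cost_delta=per_case_delta,
            annual_cost_delta=cb.annual_total - ca.annual_total,
            quadrant=classify_equity(agg_delta, per_case_delta),
        )
    return OptionComparison(option_a.name, option_b.name, per_category,
                            prof_a, prof_b, cost_a, cost_b)
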