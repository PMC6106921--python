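"""Impact-matrix quality scoring with normalization to 100, and weighted aggregation.

The score of quality domain j for a service option with parameter values x_i is

    s_j = 100 * sum_i q(i,j) * r_i / sum_i q(i,j),      r_i = min(x_i / z_i, 1)

where q(i,j) is the impact of design parameter i on domain j and z_i the
parameter's maximum beneficial value.  Setting every x_i = z_i therefore gives
s_j = 100 in every domain — 100 represents an ideal, resource-unconstrained
service.  The cap r_i <= 1 encodes "maximum beneficial": provision beyond z_i
buys no further quality.  An uncapped mode is available for exploration.

Negative impacts (a lever that harms a domain, e.g. earlier discharge harming
safety unless community care compensates) are accepted as long as each used
domain's column sum stays positive; with negative entries the 0–100 bounds no
longer hold and validation emits a warning rather than an error.

The aggregate quality score is the weight-convex combination sum_j w_j s_j
over the five Institute of Medicine domains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError, ModelSpecificationError
from .service_model import CareCategory, DesignParameterSpec

logger = logging.getLogger(__name__)

#: The five quality domains (Institute of Medicine), as used for postnatal care.
DOMAINS = ("safe", "effective", "timely", "equitable", "person_centred")

#: Default domain weights agreed through stakeholder deliberation.
DEFAULT_WEIGHTS = {
    "safe": 0.50,
    "effective": 0.30,
    "timely": 0.05,
    "equitable": 0.05,
    "person_centred": 0.10,
}

WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class ImpactMatrix:
    """Impacts q(i,j) of design parameters (rows) on quality domains (columns)."""

    table: pd.DataFrame  # index: parameter ids; columns: domain ids

    @classmethod
    def from_dict(cls, entries: Mapping[str, Mapping[str, float]],
                  domains: Iterable[str] = DOMAINS) -> "ImpactMatrix":
        """Build from ``{parameter_id: {domain_id: q}}``; missing cells are 0."""
        df = pd.DataFrame.from_dict(entries, orient="index").reindex(
            columns=list(domains)).fillna(0.0).astype(float)
        df.index.name = "parameter_id"
        return cls(df)

    @property
    def parameter_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def domain_ids(self) -> list[str]:
        return list(self.table.columns)

    def column_sum(self, domain: str) -> float:
        return float(self.table[domain].sum())

    def violations(self, specs: Iterable[DesignParameterSpec] | None = None) -> list[str]:
        out = []
        if specs is not None:
            known = {s.id for s in specs}
            for pid in self.parameter_ids:
                if pid not in known:
                    out.append(f"impact matrix references unknown parameter {pid!r}")
        for dom in self.domain_ids:
            col = self.table[dom]
            if (col != 0).any() and col.sum() <= 0:
                out.append(f"impact matrix column {dom!r} has non-positive sum "
                           f"{col.sum():g} (normalization denominator)")
        if (self.table.to_numpy() < 0).any():
            logger.warning("impact matrix contains negative entries; domain scores "
                           "are no longer bounded to [0, 100]")
        return out

    def digest(self) -> str:
        """Stable content hash, recorded in scoring-run logs for audit."""
        import hashlib
        payload = self.table.to_csv().encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass(frozen=True)
class DomainWeights:
    """Relative priority weights w_j over the quality domains; sums to 1."""

    weights: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "weights", dict(self.weights))
        bad = [d for d, w in self.weights.items() if w < 0]
        if bad:
            raise ModelSpecificationError(f"negative weights for domains {bad}")
        total = sum(self.weights.values())
        if abs(total - 1.0) > WEIGHT_TOL:
            raise ModelSpecificationError(
                f"weights must sum to 1 (got {total!r})")

    def __getitem__(self, domain: str) -> float:
        return self.weights[domain]

    def items(self):
        return self.weights.items()

    def as_dict(self) -> dict[str, float]:
        return dict(self.weights)


@dataclass(frozen=True)
class QualityProfile:
    """Per-category domain scores and weighted aggregates for one option."""

    option_name: str
    domain_scores: Mapping[str, Mapping[str, float]]  # category -> domain -> s_j
    aggregates: Mapping[str, float]                   # category -> sum_j w_j s_j

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict({c: dict(d) for c, d in self.domain_scores.items()},
                                    orient="index")
        df["aggregate"] = pd.Series(dict(self.aggregates))
        df.index.name = "category"
        return df


# ---------------------------------------------------------------------------
# Scoring operations
# ---------------------------------------------------------------------------

def score_domain(values: Mapping[str, float],
                 specs: Iterable[DesignParameterSpec],
                 matrix: ImpactMatrix,
                 domain: str,
                 cap: bool = True) -> float:
    """Score one quality domain for one category's parameter values.

    Parameters
    ----------
    values
        Mapping parameter id -> x_i for one care category.
    specs
        Design parameter specs supplying z_i; every matrix row id must resolve.
    matrix
        Impact matrix q(i,j).
    domain
        Domain id to score.
    cap
        Cap the benefit ratio x_i/z_i at 1 (default).  Uncapped scoring is
        provided for exploration only.
    """
    z = {s.id: s.max_beneficial_value for s in specs}
    denom = matrix.column_sum(domain)
    if denom <= 0:
        raise ModelSpecificationError(
            f"domain {domain!r}: impact column sum {denom:g} is not positive")
    num = 0.0
    for pid in matrix.parameter_ids:
        q = float(matrix.table.at[pid, domain])
        if q == 0.0:
            continue
        if pid not in z:
            raise ConfigurationError(
                f"impact matrix references unknown parameter {pid!r}")
        if pid not in values:
            raise ConfigurationError(
                f"no value x for parameter {pid!r}")
        r = values[pid] / z[pid]
        if cap:
            r = min(r, 1.0)
        num += q * r
    return 100.0 * num / denom


def aggregate_score(domain_scores: Mapping[str, float],
                    weights: DomainWeights) -> float:
    """Weighted aggregate sum_j w_j s_j; every weighted domain must be scored."""
    total = 0.0
    for dom, w in weights.items():
        if w == 0.0:
            continue
        if dom not in domain_scores:
            raise ConfigurationError(f"no score for weighted domain {dom!r}")
        total += w * domain_scores[dom]
    return total


def score_profile(values_by_category: Mapping[str, Mapping[str, float]],
                  specs: Iterable[DesignParameterSpec],
                  matrix: ImpactMatrix,
                  weights: DomainWeights,
                  option_name: str = "",
                  cap: bool = True) -> QualityProfile:
    """Score every domain and the aggregate for every care category."""
    specs = list(specs)
    logger.info("scoring option %r: weights=%s matrix=%s",
                option_name, weights.as_dict(), matrix.digest())
    scores: dict[str, dict[str, float]] = {}
    aggs: dict[str, float] = {}
    for cat, values in values_by_category.items():
        scores[cat] = {dom: score_domain(values, specs, matrix, dom, cap=cap)
                       for dom in matrix.domain_ids}
        aggs[cat] = aggregate_score(scores[cat], weights)
    return QualityProfile(option_name, scores, aggs)


def service_aggregate(profile: QualityProfile,
                      categories: Iterable[CareCategory]) -> float:
    """Demand-weighted mean of per-category aggregates (weights ∝ annual births)."""
    cats = list(categories)
    total_births = sum(c.annual_births for c in cats)
    if total_births <= 0:
        raise ModelSpecificationError("service aggregate undefined with zero demand")
    return sum(c.annual_births * profile.aggregates[c.id] for c in cats) / total_births


def renormalize_weights(weights: DomainWeights, domain: str,
                        new_weight: float) -> DomainWeights:
    """Set one domain's weight, scaling the others proportionally to keep sum 1.

    Every other domain j gets w_j * (1 - new_weight) / (1 - w_old), so ratios
    among untouched domains are preserved exactly.
    """
    if domain not in weights.as_dict():
        raise ConfigurationError(f"unknown domain {domain!r}")
    if not (0.0 <= new_weight <= 1.0):
        raise ModelSpecificationError(
            f"new weight for {domain!r} must lie in [0, 1], got {new_weight}")
    old = weights[domain]
    if new_weight == old:
        return weights
    if old == 1.0:
        raise ModelSpecificationError(
            f"domain {domain!r} holds all the weight; proportional split of the "
            f"remainder is undefined")
    scale = (1.0 - new_weight) / (1.0 - old)
    out = {d: (new_weight if d == domain else w * scale)
           for d, w in weights.items()}
    # guard against accumulated floating error breaking downstream validation
    drift = sum(out.values()) - 1.0
    if abs(drift) > 0:
        out[domain] -= drift if abs(drift) <= WEIGHT_TOL else 0.0
    return DomainWeights(out)
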