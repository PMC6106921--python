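"""Acuity-transition sub-model: how hospital stay shifts the discharge mix.

While a mother and baby remain on the postnatal ward their acuity tends to
fall, so longer stays discharge relatively fewer high-acuity dyads into the
community.  The sub-model here is a linear decay chain over the ordered acuity
categories (lowest to highest): each category k transfers probability mass to
the adjacent lower-acuity category k-1 at a constant per-hour decay rate.
The chain is solved in closed form with the matrix exponential, so results are
exact for any stay length; tests cross-check against an independent
small-step mass-transfer simulation.

The decay rates are user-configurable — the functional form stands in for a
site-specific statistical fit against workforce data, which individual
deployments should re-estimate.  The whole sub-model is optional: quality
scoring and costing run without it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.linalg import expm

from .errors import ModelSpecificationError
from .service_model import CareCategory, ServiceOption

MIX_TOL = 1e-9


@dataclass(frozen=True)
class AcuityMix:
    """A probability distribution over acuity categories."""

    proportions: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "proportions", dict(self.proportions))
        bad = [c for c, p in self.proportions.items() if not (p >= 0)]
        if bad:
            raise ModelSpecificationError(f"negative proportions for {bad}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > MIX_TOL:
            raise ModelSpecificationError(
                f"acuity proportions must sum to 1 (got {total!r})")

    def __getitem__(self, category: str) -> float:
        return self.proportions[category]

    def as_dict(self) -> dict[str, float]:
        return dict(self.proportions)


@dataclass(frozen=True)
class TransitionParameters:
    """Ordered acuity categories and per-category downward decay rates.

    ``order`` lists category ids from lowest to highest acuity; ``decay_rate``
    gives each category's per-hour rate of mass transfer to the next-lower
    category.  The lowest category has nowhere lower to go, so its rate is
    ignored (and must be 0 if given).
    """

    order: tuple[str, ...]
    decay_rate_per_hour: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "order", tuple(self.order))
        object.__setattr__(self, "decay_rate_per_hour",
                           dict(self.decay_rate_per_hour))
        for cat, rate in self.decay_rate_per_hour.items():
            if not (rate >= 0):
                raise ModelSpecificationError(
                    f"decay rate for {cat!r} must be >= 0, got {rate}")
        lowest = self.order[0]
        if self.decay_rate_per_hour.get(lowest, 0.0) != 0.0:
            raise ModelSpecificationError(
                f"lowest-acuity category {lowest!r} cannot decay further; "
                f"its rate must be 0")

    def generator(self) -> np.ndarray:
        """Continuous-time generator A with dP/dt = A @ P over ``order``."""
        n = len(self.order)
        A = np.zeros((n, n))
        for k in range(1, n):
            lam = self.decay_rate_per_hour.get(self.order[k], 0.0)
            A[k, k] -= lam
            A[k - 1, k] += lam
        return A


def discharge_mix(admission_mix: AcuityMix, stay_hours: float,
                  params: TransitionParameters) -> AcuityMix:
    """Acuity mix at discharge after ``stay_hours`` on the postnatal ward.

    Mass only moves downward, so the result is stochastically no higher in
    acuity than the admission mix, and the high-acuity share is non-increasing
    in stay length.  Zero stay (or all-zero rates) returns the admission mix.
    """
    if not (stay_hours >= 0):
        raise ModelSpecificationError(f"stay_hours must be >= 0, got {stay_hours}")
    missing = [c for c in params.order if c not in admission_mix.proportions]
    if missing:
        raise ModelSpecificationError(
            f"admission mix missing categories {missing}")
    p0 = np.array([admission_mix[c] for c in params.order])
    pt = expm(params.generator() * stay_hours) @ p0
    pt = np.clip(pt, 0.0, None)
    pt /= pt.sum()
    return AcuityMix(dict(zip(params.order, pt)))


def discharge_demand(option: ServiceOption,
                     categories: Iterable[CareCategory],
                     params: TransitionParameters,
                     ) -> dict[str, float]:
    """Annual demand per category at discharge into the community.

    Each category's admission cohort evolves under the decay chain for that
    category's own hospital stay; the discharged cohorts are then summed.
    Total demand is conserved.  Intended as the ``community_births`` argument
    of :func:`caredesign.costs.annual_cost`.
    """
    cats = {c.id: c for c in categories}
    out = {cid: 0.0 for cid in params.order}
    for cid in params.order:
        cat = cats.get(cid)
        if cat is None or cat.annual_births == 0:
            continue
        start = AcuityMix({c: (1.0 if c == cid else 0.0) for c in params.order})
        stay = option.hospital[cid].length_of_stay_hours
        mix = discharge_mix(start, stay, params)
        for c, p in mix.as_dict().items():
            out[c] += cat.annual_births * p
    return out
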