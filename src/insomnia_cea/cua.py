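"""Cost-utility metrics and population scaling.

Per person treated, the net benefit of treatment is the health cost avoided
(the insomniac/non-insomniac per-capita spend gap) minus the treatment cost,
and the net benefit per QALY gained divides that by the utility gain. With a
one-year horizon and no discounting, a utility difference equals QALYs
gained. National totals scale the per-person figures by the number treated,

    n_treated = at-risk population × prevalence × proportion seeking care.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "UtilitySource",
    "UtilityObservation",
    "QalyGainSpec",
    "PopulationScaling",
    "EvaluationResult",
    "sf36_to_utility",
    "combine_utility_dataset",
    "evaluate",
]


class UtilitySource(str, Enum):
    SF36_DOMAINS = "sf36_domains"
    EQ5D = "eq5d"


@dataclass(frozen=True)
class UtilityObservation:
    """One utility-difference observation (post−pre, or deficit vs good sleepers)."""

    source: UtilitySource
    value: float

    def __post_init__(self):
        if not -1.0 <= self.value <= 1.0:
            raise ValueError(f"utility difference {self.value!r} outside [-1, 1]")


@dataclass(frozen=True)
class QalyGainSpec:
    """Low / base / high utility gain for base case and sensitivity."""

    low: float
    base: float
    high: float

    def __post_init__(self):
        if not (self.low <= self.base <= self.high):
            raise ValueError("require low <= base <= high")
        if self.low < 0:
            raise ValueError("low must be non-negative")


@dataclass(frozen=True)
class PopulationScaling:
    """At-risk population (millions) with prevalence and care-seeking rates."""

    at_risk: float
    prevalence: float
    p_seek: float

    def __post_init__(self):
        if self.at_risk <= 0:
            raise ValueError("at-risk population must be positive")
        for name in ("prevalence", "p_seek"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v!r} outside [0, 1]")

    @property
    def n_treated(self) -> float:
        """Persons seeking treatment, in millions."""
        return self.at_risk * self.prevalence * self.p_seek


@dataclass(frozen=True)
class EvaluationResult:
    """Per-person and population-scaled evaluation of treatment vs none.

    Dollar fields are NZD; population totals are in millions (dollars or
    QALYs), matching the per-million scaling of ``n_treated``.
    """

    cost_per_person: float
    avoided_per_person: float
    net_benefit_per_person: float
    qaly_gain: float
    cost_per_qaly: float
    n_treated: float
    total_cost: float
    total_avoided: float
    total_net_benefit: float
    total_qalys: float


def sf36_to_utility(physical: float, mental: float) -> float:
    """Rescale two 0–100 SF-36 domain scores to 0–1 and average them."""
    for name, score in (("physical", physical), ("mental", mental)):
        if not 0.0 <= score <= 100.0:
            raise ValueError(f"{name} score {score!r} outside [0, 100]")
    return (physical / 100.0 + mental / 100.0) / 2.0


def combine_utility_dataset(
    observations: Iterable[UtilityObservation] | Sequence[float],
) -> QalyGainSpec:
    """Pool utility-difference observations into a low/base/high gain spec.

    The base case is the mean, the high value the maximum, and zero is
    assumed for the low value (a treatment that fails to improve utility).
    Accepts either :class:`UtilityObservation` records or bare floats.
    """
    values = [
        o.value if isinstance(o, UtilityObservation) else float(o)
        for o in observations
    ]
    if not values:
        raise ValueError("need at least one utility observation")
    return QalyGainSpec(low=0.0, base=statistics.fmean(values), high=max(values))


def evaluate(
    cost_per_person: float,
    avoided_per_person: float,
    qaly_gain: float,
    scaling: PopulationScaling,
) -> EvaluationResult:
    """Net benefit, cost per QALY and national totals for one parameter set.

    Treatment success is already embedded in the pathway model (termination
    nodes assume a successful outcome), so no separate success rate is
    applied here. Raises ``ValueError`` for a zero QALY gain, where cost
    per QALY is undefined.
    """
    if cost_per_person < 0 or avoided_per_person < 0:
        raise ValueError("dollar inputs must be non-negative")
    if qaly_gain <= 0:
        raise ValueError("cost per QALY undefined for non-positive QALY gain")
    net = avoided_per_person - cost_per_person
    n = scaling.n_treated
    return EvaluationResult(
        cost_per_person=cost_per_person,
        avoided_per_person=avoided_per_person,
        net_benefit_per_person=net,
        qaly_gain=qaly_gain,
        cost_per_qaly=net / qaly_gain,
        n_treated=n,
        total_cost=cost_per_person * n,
        total_avoided=avoided_per_person * n,
        total_net_benefit=net * n,
        total_qalys=qaly_gain * n,
    )
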