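"""Split national per-capita health spend into insomniac / non-insomniac means.

Let TP be the all-population per-capita health cost, Ip the insomnia
prevalence, and R the ratio of insomniac to non-insomniac per-capita cost.
Writing Y for the non-insomniac mean and X = R·Y for the insomniac mean,
the population mean is the prevalence-weighted mixture

    TP = Ip·X + (1 − Ip)·Y  =  Y·(1 + Ip·(R − 1)),

so Y = TP / (1 + Ip·(R − 1)). The per-capita health cost avoided by
successful treatment is the gap delta = X − Y = (R − 1)·Y.

Base-case R is 1.18 (an 18% cost increase); the literature-supported
plausible range for the increase is 5–25%.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "COST_INCREASE_BASE",
    "COST_INCREASE_RANGE",
    "PopulationHealthCosts",
    "per_capita_cost",
    "split_costs",
    "recover_ratio",
]

#: base-case proportional cost increase for insomniacs vs good sleepers
COST_INCREASE_BASE = 0.18
#: plausible literature range for that increase (outliers removed)
COST_INCREASE_RANGE = (0.05, 0.25)


@dataclass(frozen=True)
class PopulationHealthCosts:
    """Per-capita health-cost decomposition by insomnia status.

    Attributes
    ----------
    TP : all-population mean ($ per capita)
    Ip : insomnia prevalence (proportion)
    R : insomniac:non-insomniac cost ratio
    Y : non-insomniac mean ($ per capita)
    X : insomniac mean ($ per capita), X = R·Y
    delta : cost gap X − Y ($ per capita)
    """

    TP: float
    Ip: float
    R: float
    Y: float
    X: float
    delta: float


def per_capita_cost(total_spend: float, population: float) -> float:
    """Per-capita cost from total spend ($M) and population (M persons)."""
    if population <= 0:
        raise ValueError("population must be positive")
    return total_spend / population


def split_costs(TP: float, Ip: float, R: float) -> PopulationHealthCosts:
    """Decompose the population mean TP into X and Y given prevalence and ratio."""
    if not 0.0 <= Ip <= 1.0:
        raise ValueError(f"prevalence {Ip!r} outside [0, 1]")
    if R <= 0:
        raise ValueError(f"cost ratio {R!r} must be positive")
    Y = TP / (1.0 + Ip * (R - 1.0))
    X = R * Y
    return PopulationHealthCosts(TP=TP, Ip=Ip, R=R, Y=Y, X=X, delta=X - Y)


def recover_ratio(costs: PopulationHealthCosts) -> float:
    """Inverse check: X / Y round-trips with :func:`split_costs`."""
    if costs.Y == 0:
        raise ValueError("non-insomniac mean is zero; ratio undefined")
    return costs.X / costs.Y
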