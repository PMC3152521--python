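"""Probabilistic sensitivity analysis by Monte Carlo over triangular ranges.

Every uncertain input gets a triangular (low, mode, high) distribution —
the standard choice when only a best guess and plausible limits are known;
by default limits are the base case ±25%. Each iteration draws one value
per parameter (a single seeded generator stream, parameters sampled in
their listed order), evaluates the full model on the sampled set, and the
resulting output samples are summarised by mean and empirical percentiles
(linear interpolation between order statistics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "TriangularParam",
    "SimulationSpec",
    "SimulationResult",
    "triangular_mean",
    "make_default_range",
    "sample_triangular",
    "run_monte_carlo",
    "summarize",
]


@dataclass(frozen=True)
class TriangularParam:
    """Triangular uncertainty range for one named model input."""

    low: float
    mode: float
    high: float
    target: str = ""

    def __post_init__(self):
        if not (self.low <= self.mode <= self.high):
            raise ValueError(
                f"{self.target or 'param'}: require low <= mode <= high, "
                f"got ({self.low}, {self.mode}, {self.high})"
            )

    @property
    def degenerate(self) -> bool:
        return self.low == self.high


def triangular_mean(param: TriangularParam) -> float:
    """Analytic mean (low + mode + high) / 3."""
    return (param.low + param.mode + param.high) / 3.0


def make_default_range(
    base: float, fraction: float = 0.25, target: str = ""
) -> TriangularParam:
    """Symmetric ±``fraction`` triangular range about ``base``.

    A zero base yields a degenerate (zero-width) range, which is rejected:
    callers must treat exactly-zero inputs as fixed rather than sampled.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction {fraction!r} outside (0, 1)")
    if base == 0:
        raise ValueError("zero base gives a degenerate range; hold it fixed instead")
    lo, hi = base * (1.0 - fraction), base * (1.0 + fraction)
    if lo > hi:  # negative base
        lo, hi = hi, lo
    return TriangularParam(low=lo, mode=base, high=hi, target=target)


def sample_triangular(param: TriangularParam, u: float) -> float:
    """Inverse-CDF transform of a uniform deviate ``u`` in [0, 1]."""
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"uniform deviate {u!r} outside [0, 1]")
    lo, m, hi = param.low, param.mode, param.high
    span = hi - lo
    if span == 0.0:
        return lo
    f = (m - lo) / span
    if u <= f:
        return lo + math.sqrt(u * span * (m - lo))
    return hi - math.sqrt((1.0 - u) * span * (hi - m))


@dataclass(frozen=True)
class SimulationSpec:
    """Monte Carlo design: iteration count, seed, and parameter ranges."""

    params: Sequence[TriangularParam]
    n_iterations: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        targets = [p.target for p in self.params]
        if len(set(targets)) != len(targets):
            raise ValueError("parameter targets must be unique")


@dataclass
class SimulationResult:
    """Per-output sample arrays plus bookkeeping of invalid iterations."""

    samples: dict[str, np.ndarray]
    n_iterations: int
    n_invalid: int = 0
    invalid_messages: list[str] = field(default_factory=list)

    @property
    def outputs(self) -> list[str]:
        return list(self.samples)

    def mean(self, output: str) -> float:
        return float(np.mean(self.samples[output]))

    def percentile(self, output: str, q: float) -> float:
        """Empirical quantile at probability ``q`` (linear interpolation)."""
        return float(np.quantile(self.samples[output], q))

    def summary(self, interval: float = 0.90) -> dict[str, tuple[float, float, float]]:
        return {out: summarize(self, interval, output=out) for out in self.outputs}


class _IterationInvalid(Exception):
    """Raised by a model closure when a sampled parameter set is unusable."""


def run_monte_carlo(
    model: Callable[[Mapping[str, float]], Mapping[str, float]],
    spec: SimulationSpec,
) -> SimulationResult:
    """Propagate parameter uncertainty through ``model``.

    ``model`` maps a dict {target: sampled value} to a dict of named
    numeric outputs and must be deterministic given its inputs; all
    randomness lives in the parameter draws. Identical specs produce
    bitwise-identical results. Iterations whose sampled set the model
    rejects (``ValueError``) are recorded in ``n_invalid`` — never
    silently dropped — and excluded from the sample arrays.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[Mapping[str, float]] = []
    n_invalid = 0
    messages: list[str] = []
    for _ in range(spec.n_iterations):
        drawn = {
            p.target: sample_triangular(p, rng.uniform()) for p in spec.params
        }
        try:
            rows.append(model(drawn))
        except ValueError as exc:
            n_invalid += 1
            if len(messages) < 10:
                messages.append(str(exc))
    if not rows:
        raise RuntimeError(
            f"all {spec.n_iterations} iterations invalid; first: {messages[:1]}"
        )
    outputs = list(rows[0])
    samples = {
        out: np.asarray([row[out] for row in rows], dtype=float)
        for out in outputs
    }
    return SimulationResult(
        samples=samples,
        n_iterations=spec.n_iterations,
        n_invalid=n_invalid,
        invalid_messages=messages,
    )


def summarize(
    result: SimulationResult | Sequence[float] | np.ndarray,
    interval: float = 0.90,
    output: str | None = None,
) -> tuple[float, float, float]:
    """(lower, upper, mean) with lower/upper the central ``interval`` bounds.

    For a 90% interval these are the 5th and 95th empirical percentiles.
    Accepts a raw sample sequence or a :class:`SimulationResult` (with
    ``output`` naming which sample array; defaults to the first).
    """
    if not 0.0 < interval <= 1.0:
        raise ValueError(f"interval {interval!r} outside (0, 1]")
    if isinstance(result, SimulationResult):
        key = output if output is not None else result.outputs[0]
        values = result.samples[key]
    else:
        values = np.asarray(result, dtype=float)
    if values.size == 0:
        raise ValueError("no samples to summarise")
    alpha = (1.0 - interval) / 2.0
    lower = float(np.quantile(values, alpha))
    upper = float(np.quantile(values, 1.0 - alpha))
    return lower, upper, float(np.mean(values))
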