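"""Synthetic inputs for the property suites.

No empirical dataset underlies this model, so the test fixtures are
(i) random admissible parameter draws anchored to the literature value
table — interval-valued parameters drawn uniformly from their intervals,
point-valued parameters jittered by up to +/-20%, doses drawn from the
envelope of the published application doses — and (ii) scalar linear Caputo
decay problems ``D^alpha y = -rate*y`` whose closed form
``y0 * E_alpha(-rate * t^alpha)`` serves as solver oracle.

All randomness is seed-explicit; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .model import ModelParameters, PARAMETER_RANGES
from .solver import mittag_leffler

__all__ = ["DrawSpec", "default_ranges", "draw_parameters",
           "LinearTestProblem", "linear_test_problem"]

_POINT_VALUES = {
    "s1": 1000.0, "s2": 50.0, "s3": 50.0, "s4": 50.0,
    "r1": 0.3, "r2": 0.7, "beta1": 0.1, "omega": 0.3,
    "beta2": 0.5, "beta3": 0.4, "beta4": 0.7,
    "d1": 0.008, "d2": 0.0008, "d3": 0.0001,
    "vartheta": 1.0, "b": 0.25,
}
_DOSE_RANGE = (0.0, 0.6)  # envelope of the published application doses
_JITTER = 0.20


def default_ranges() -> dict[str, tuple[float, float]]:
    """Per-parameter draw intervals: literature intervals where given,
    +/-20% jitter around the point values otherwise, [0, 0.6] for doses."""
    ranges: dict[str, tuple[float, float]] = dict(PARAMETER_RANGES)
    for name, v in _POINT_VALUES.items():
        ranges[name] = ((1.0 - _JITTER) * v, (1.0 + _JITTER) * v)
    for u in ("u1", "u2", "u3"):
        ranges[u] = _DOSE_RANGE
    return ranges


@dataclass(frozen=True)
class DrawSpec:
    """Seeded specification for random admissible parameter draws."""

    seed: int
    n: int = 1
    ranges: Mapping[str, tuple[float, float]] | None = None

    def resolved_ranges(self) -> dict[str, tuple[float, float]]:
        ranges = default_ranges()
        if self.ranges:
            for k, (lo, hi) in self.ranges.items():
                if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                    raise ValueError(f"malformed range for {k}: {(lo, hi)}")
                ranges[k] = (float(lo), float(hi))
        return ranges


def draw_parameters(spec: DrawSpec) -> list[ModelParameters]:
    """Uniform, seed-deterministic draws of admissible parameter sets."""
    rng = np.random.default_rng(spec.seed)
    ranges = spec.resolved_ranges()
    keys = sorted(ranges)  # fixed order => reproducibility
    out = []
    for _ in range(spec.n):
        kw = {k: float(rng.uniform(*ranges[k])) for k in keys}
        out.append(ModelParameters(**kw))
    return out


@dataclass(frozen=True)
class LinearTestProblem:
    """``D^alpha y = -rate*y`` with closed form y0*E_alpha(-rate t^alpha)."""

    alpha: float
    rate: float
    y0: float

    @property
    def field(self) -> Callable[[np.ndarray], np.ndarray]:
        rate = self.rate
        return lambda y: -rate * np.asarray(y, dtype=float)

    def exact(self, t: float) -> float:
        if self.rate == 0.0:
            return self.y0
        return self.y0 * mittag_leffler(self.alpha, -self.rate * t ** self.alpha)


def linear_test_problem(alpha: float, rate: float, y0: float) -> LinearTestProblem:
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return LinearTestProblem(alpha=alpha, rate=rate, y0=y0)
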