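"""Well-posedness diagnostics: Lipschitz constants and Picard iteration.

The existence/uniqueness argument for the fractional system proceeds through
the Volterra integral form

    x(t) = x0 + sigma^(1-alpha)/Gamma(alpha)
                * int_0^t K(x(s)) (t-s)^(alpha-1) ds

and per-equation Lipschitz constants of the kernels under sup-norm state
bounds ||T|| < b1, ..., ||P|| < b5:

    L1 = g1 + u3 + 2 b1 g1/s1 + beta1 b2/s2 + omega b4/s4
    L2 = beta2 + d1,  L3 = beta3 + d2,
    L4 = beta4 + d3 + delta + u2,  L5 = vartheta.

Uniqueness holds when 1 - sigma^(1-alpha)/Gamma(alpha) * L_i >= 0 for every
equation.  That condition is implemented literally as stated in the source
analysis; it carries no horizon factor, so the Picard demonstrator below is
meant for unit-scale horizons where the literal condition is meaningful.
The horizon-bearing variant 1 - sigma^(1-alpha) t^alpha L_i/Gamma(alpha+1)
(the usual contraction constant of the fractional Volterra operator) is
reported alongside for comparison.

``picard_iterate`` performs successive substitution into the integral form
with a product-rectangle quadrature (exact for constant kernels) and records
the sup-norms of the successive differences Psi_n = x_n - x_{n-1}; when the
uniqueness flags hold on the tested horizon those norms shrink geometrically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.special import gamma as _gamma

from .model import ModelParameters, FractionalConfig, make_field
from .solver import SolverGrid, TrajectorySolution

__all__ = [
    "LipschitzReport",
    "PicardSequence",
    "default_bounds",
    "lipschitz_constants",
    "bounds_from_trajectory",
    "picard_iterate",
    "fractional_quadrature",
]

BLOWUP_LIMIT = 1e12


def default_bounds(params: ModelParameters) -> tuple[float, ...]:
    """Generous sup-norm envelopes (b1..b5) of the scenario trajectories."""
    b5 = 2.0 * params.u1 / params.vartheta + 1.0
    return (params.s1, 2.0, 2.0, 10.0, b5)


@dataclass
class LipschitzReport:
    """Per-kernel Lipschitz constants and uniqueness flags."""

    bounds: tuple[float, ...]           # (b1..b5)
    constants: tuple[float, ...]        # (L1..L5)
    l_star: float                       # max L_i
    bound_a: float                      # comparison constant (must dominate L_i)
    uniqueness_flags: tuple[bool, ...]  # 1 - s^(1-a)/Gamma(a) L_i >= 0, literal
    horizon_flags: tuple[bool, ...]     # horizon-bearing variant at t = 1
    alpha: float
    sigma: float

    @property
    def lipschitz_ok(self) -> bool:
        return all(l < self.bound_a for l in self.constants)

    @property
    def unique(self) -> bool:
        return all(self.uniqueness_flags)

    def to_json(self) -> str:
        return json.dumps({
            "bounds": list(self.bounds),
            "constants": list(self.constants),
            "l_star": self.l_star,
            "bound_a": self.bound_a,
            "uniqueness_flags": [bool(f) for f in self.uniqueness_flags],
            "horizon_flags": [bool(f) for f in self.horizon_flags],
            "alpha": self.alpha,
            "sigma": self.sigma,
        })

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def lipschitz_constants(params: ModelParameters,
                        bounds: Sequence[float] | None = None,
                        alpha: float = 1.0,
                        sigma: float = 1.0,
                        bound_a: float | None = None) -> LipschitzReport:
    """Compute L1..L5 and the uniqueness flags for given state bounds."""
    p = params
    if bounds is None:
        bounds = default_bounds(p)
    b1, b2, b3, b4, b5 = (float(b) for b in bounds)
    if min(b1, b2, b3, b4, b5) <= 0:
        raise ValueError("state bounds must be positive")
    cfg = FractionalConfig(alpha=alpha, sigma=sigma)  # validates alpha/sigma

    l1 = p.g1 + p.u3 + 2.0 * b1 * p.g1 / p.s1 + p.beta1 * b2 / p.s2 \
        + p.omega * b4 / p.s4
    l2 = p.beta2 + p.d1
    l3 = p.beta3 + p.d2
    l4 = p.beta4 + p.d3 + p.delta + p.u2
    l5 = p.vartheta
    constants = (l1, l2, l3, l4, l5)
    l_star = max(constants)
    if bound_a is None:
        bound_a = 1.0 + l_star

    coef = cfg.scale / _gamma(alpha)
    flags = tuple(1.0 - coef * l >= 0.0 for l in constants)
    coef_h = cfg.scale / _gamma(alpha + 1.0)  # t = 1 horizon
    horizon_flags = tuple(1.0 - coef_h * l >= 0.0 for l in constants)
    return LipschitzReport(
        bounds=(b1, b2, b3, b4, b5), constants=constants, l_star=l_star,
        bound_a=float(bound_a), uniqueness_flags=flags,
        horizon_flags=horizon_flags, alpha=alpha, sigma=sigma)


def bounds_from_trajectory(traj: TrajectorySolution,
                           margin: float = 1.05) -> tuple[float, ...]:
    """Sup-norms of the five components along a trajectory (times a margin)."""
    sup = np.max(np.abs(traj.states), axis=0)
    return tuple(float(margin * s) if s > 0 else 1e-12 for s in sup)


def fractional_quadrature(values: np.ndarray, alpha: float, h: float) -> np.ndarray:
    """Product-rectangle Riemann-Liouville quadrature on a uniform grid.

    Returns ``I[k] ~ 1/Gamma(alpha) int_0^{t_k} f(s) (t_k - s)^(alpha-1) ds``
    using the left-rectangle product rule; exact for constant ``f``.
    ``values`` has shape (n+1, d) (f at the grid points).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0] - 1
    m = np.arange(n + 1, dtype=float)
    pw = m ** alpha
    w = (pw[1:] - pw[:-1]) * h ** alpha / alpha  # weight for lag m >= 1
    out = np.zeros_like(values)
    for k in range(1, n + 1):
        out[k] = np.dot(w[k - 1::-1], values[:k])
    return out / _gamma(alpha)


@dataclass
class PicardSequence:
    """Successive-approximation iterates of the Volterra integral form."""

    times: np.ndarray
    iterates: list[np.ndarray]          # each (n+1, d)
    successive_diffs: np.ndarray        # (n_iter, d) sup-norm Psi per component
    converged: bool
    blowup: bool
    alpha: float
    sigma: float

    def final(self) -> np.ndarray:
        return self.iterates[-1]

    def save_csv(self, directory, prefix: str = "picard") -> None:
        import pandas as pd
        from .model import STATE_NAMES
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, it in enumerate(self.iterates):
            cols = STATE_NAMES if it.shape[1] == 5 else \
                [f"x{j}" for j in range(it.shape[1])]
            df = pd.DataFrame(it, columns=list(cols))
            df.insert(0, "t", self.times)
            df.to_csv(directory / f"{prefix}_{i:02d}.csv", index=False)


def picard_iterate(params_or_field,
                   x0,
                   config: FractionalConfig,
                   grid: SolverGrid,
                   n_iter: int = 8,
                   variant: str = "base") -> PicardSequence:
    """Picard successive approximations of the integral form.

    ``x_0(t) = x0``;
    ``x_{n+1}(t_k) = x0 + sigma^(1-alpha)/Gamma(alpha) *
    product-rectangle quadrature of K(x_n)(t_k - s)^(alpha-1)``.

    First argument is either a ``ModelParameters`` (the full model field is
    built, sigma-scaled) or a raw vector-field callable (assumed already
    scaled).  Records sup-norm successive differences per component.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    if isinstance(params_or_field, ModelParameters):
        fld: Callable[[np.ndarray], np.ndarray] = make_field(
            params_or_field, config, variant=variant)
    else:
        fld = params_or_field

    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    d = x0.shape[0]
    n = grid.n_steps
    times = grid.times()
    current = np.tile(x0, (n + 1, 1))
    iterates = [current.copy()]
    diffs = []
    blowup = False
    for _ in range(n_iter):
        kvals = np.apply_along_axis(fld, 1, current)
        nxt = x0[None, :] + fractional_quadrature(kvals, config.alpha, grid.h)
        diffs.append(np.max(np.abs(nxt - current), axis=0))
        current = nxt
        iterates.append(current.copy())
        if np.max(np.abs(current)) > BLOWUP_LIMIT:
            blowup = True
            break
    diffs = np.asarray(diffs)
    tail = diffs[-1]
    prev = diffs[-2] if diffs.shape[0] >= 2 else tail
    converged = bool(not blowup and np.all(tail <= prev + 1e-15))
    return PicardSequence(times=times, iterates=iterates,
                          successive_diffs=diffs, converged=converged,
                          blowup=blowup, alpha=config.alpha,
                          sigma=config.sigma)
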