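"""Equilibria of the base tumor-immune-probiotic system.

Two equilibrium families exist:

* the tumor-free equilibrium ``E1* = (0, 0, G*, C*, P*)`` in closed form, and
* coexistence equilibria ``E2*`` with ``T* > 0``, found by reducing the
  fixed-point system to a scalar equation in ``T`` and root-finding.

Setting every rate to zero and eliminating gives

    P* = u1 / vartheta
    G*(T) = (r1 + g3*T/(s3+T)) / (beta3 + d2)
    M*(T) = g2*T / ((beta2 + d1) * (s2 + T))
    C*(T) = (r2 + g4*G*(T)) / D_C,
    D_C   = beta4 + d3 - u2 - delta*P*/(b + P*)

(the CD4 balance denominator ``D_C`` must be positive for an admissible CD4
level), and the tumor line divided by ``T`` leaves the scalar condition

    g1*(1 - T/s1) - beta1*M*(T)/(s2+T) - omega*C*(T)/(s4+T) - u3 = 0.

This re-derived reduction is the default (``mode="corrected"``).  A second
mode, ``mode="paper_verbatim"``, evaluates the scalar equation in the form it
circulates in the source literature, whose third term uses the dendritic
branch in place of the CD4 branch (an apparent label swap); the two modes are
arbitrated objectively by the residual of the full system, which only the
corrected reduction satisfies.

Every reported equilibrium carries the max-norm residual of the full
right-hand side evaluated at it; ``exists`` implies residual < 1e-9.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .model import ModelParameters, StateVector, rhs_base

__all__ = [
    "EquilibriumReport",
    "cd4_denominator",
    "tumor_free_equilibrium",
    "coexistence_scalar",
    "find_coexistence",
]

RESIDUAL_TOL = 1e-9


@dataclass
class EquilibriumReport:
    """An equilibrium point with existence flags and residual norm."""

    kind: str                     # "tumor_free" | "coexistence"
    state: StateVector | None
    residual: float
    exists: bool
    positivity: bool
    notes: str = ""

    def as_array(self) -> np.ndarray:
        if self.state is None:
            raise ValueError("no admissible equilibrium state")
        return self.state.as_array()

    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "state": None if self.state is None else list(self.as_array()),
            "residual": self.residual,
            "exists": self.exists,
            "positivity": self.positivity,
            "notes": self.notes,
        }
        return json.dumps(payload)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def cd4_denominator(params: ModelParameters) -> float:
    """CD4 balance denominator D_C = beta4 + d3 - u2 - delta*P*/(b+P*)."""
    p = params
    p_star = p.u1 / p.vartheta
    return p.beta4 + p.d3 - p.u2 - p.delta * p_star / (p.b + p_star)


def _residual(state: np.ndarray, params: ModelParameters) -> float:
    return float(np.max(np.abs(rhs_base(state, params))))


def tumor_free_equilibrium(params: ModelParameters) -> EquilibriumReport:
    """Closed-form tumor-free equilibrium (T = M = 0)."""
    p = params
    p_star = p.u1 / p.vartheta
    g_star = p.r1 / (p.beta3 + p.d2)
    d_c = cd4_denominator(p)
    if d_c <= 0:
        return EquilibriumReport(
            kind="tumor_free", state=None, residual=np.inf,
            exists=False, positivity=False,
            notes="CD4 balance denominator nonpositive - no admissible "
                  "tumor-free equilibrium",
        )
    c_star = (p.r2 + p.g4 * g_star) / d_c
    state = np.array([0.0, 0.0, g_star, c_star, p_star])
    res = _residual(state, p)
    return EquilibriumReport(
        kind="tumor_free", state=StateVector.from_array(state),
        residual=res, exists=res < RESIDUAL_TOL,
        positivity=bool(np.all(state >= 0)),
    )


def _branches(T, params: ModelParameters):
    """Back-substituted M*(T), G*(T), C*(T) along the corrected reduction."""
    p = params
    d_c = cd4_denominator(p)
    if d_c <= 0:
        raise ValueError("no admissible C branch: CD4 balance denominator <= 0")
    T = np.asarray(T, dtype=float)
    m = p.g2 * T / ((p.beta2 + p.d1) * (p.s2 + T))
    g = (p.r1 + p.g3 * T / (p.s3 + T)) / (p.beta3 + p.d2)
    c = (p.r2 + p.g4 * g) / d_c
    return m, g, c


def coexistence_scalar(T, params: ModelParameters, mode: str = "corrected"):
    """Scalar equilibrium condition f(T) whose positive roots are T2*.

    ``mode="corrected"`` (default) uses the reduction re-derived from the
    full fixed-point system; ``mode="paper_verbatim"`` evaluates the printed
    variant (dendritic branch in the CD4 slot).  Vectorized over ``T``.
    """
    p = params
    T = np.asarray(T, dtype=float)
    logistic = p.g1 * (1.0 - T / p.s1) - p.u3
    if mode == "corrected":
        m, _, c = _branches(T, p)
        out = logistic - p.beta1 * m / (p.s2 + T) - p.omega * c / (p.s4 + T)
    elif mode == "paper_verbatim":
        out = (
            logistic
            - p.beta1 * p.g2 * T / ((p.beta2 + p.d1) * (p.s2 + T) ** 2)
            - (p.omega * p.r1 * (p.s3 + T) + p.omega * p.g3 * T)
            / ((p.beta3 + p.d2) * (p.s3 + T) * (p.s4 + T))
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if out.shape else float(out)


def find_coexistence(params: ModelParameters, mode: str = "corrected",
                     scan_points: int = 10_000) -> list[EquilibriumReport]:
    """All admissible coexistence equilibria on (0, s1].

    Scans the scalar condition on a uniform grid, brackets each sign change,
    polishes with Brent's method, back-substitutes the remaining components
    and verifies the full-system residual.  Returns an empty list when no
    admissible root exists.
    """
    if scan_points < 100:
        raise ValueError("scan_points must be >= 100")
    p = params
    try:
        f = lambda T: coexistence_scalar(T, p, mode=mode)
        grid = np.linspace(p.s1 / scan_points, p.s1, scan_points)
        vals = np.asarray(f(grid))
    except ValueError:
        return []

    roots: list[float] = []
    sign = np.sign(vals)
    exact = np.flatnonzero(vals == 0.0)
    roots.extend(grid[exact])
    idx = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    for i in idx:
        r = brentq(f, grid[i], grid[i + 1], xtol=1e-13, rtol=8.9e-16)
        roots.append(float(r))

    # merge near-duplicates
    roots.sort()
    merged: list[float] = []
    for r in roots:
        if not merged or r - merged[-1] > 1e-6 * p.s1:
            merged.append(r)

    reports: list[EquilibriumReport] = []
    for t_star in merged:
        if t_star <= 0:
            continue
        m, g, c = _branches(t_star, p)
        state = np.array([t_star, float(m), float(g), float(c),
                          p.u1 / p.vartheta])
        if not np.all(np.isfinite(state)):
            reports.append(EquilibriumReport(
                kind="coexistence", state=None, residual=np.inf,
                exists=False, positivity=False,
                notes=f"non-finite back-substitution at T*={t_star:.6g}"))
            continue
        if np.any(state < 0):
            reports.append(EquilibriumReport(
                kind="coexistence", state=None, residual=np.inf,
                exists=False, positivity=False,
                notes=f"negative component at T*={t_star:.6g}"))
            continue
        res = _residual(state, p)
        reports.append(EquilibriumReport(
            kind="coexistence", state=StateVector.from_array(state),
            residual=res, exists=res < RESIDUAL_TOL, positivity=True,
            notes="" if res < RESIDUAL_TOL else
            f"scalar root does not satisfy the full system "
            f"(residual {res:.3g}); mode={mode}"))
    return [r for r in reports if r.exists or r.notes]
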