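"""Linearized stability of model equilibria.

Builds the 5x5 Jacobian of the (scaled) right-hand side, extracts the
characteristic quantities of the (T, M, G, C) block whose quartic

    lambda^4 - R1 lambda^3 + R2 lambda^2 + R3 lambda + R4 = 0

determines four of the five roots (the probiotic row decouples and always
contributes ``-vartheta``), forms the Hurwitz determinants

    H1 = -R1,  H2 = -R1 R2 - R3,
    H3 = -R1 R2 R3 - R1^2 R4 - R3^2,  H4 = R4 H3,

and classifies the equilibrium.  For fractional order ``alpha`` the primary
classifier is Matignon's criterion: asymptotic stability iff every
eigenvalue satisfies ``|arg(lambda)| > alpha*pi/2`` (which reduces to
``Re lambda < 0`` at alpha = 1).  Routh-Hurwitz positivity of H1..H4 is the
alpha-independent sufficient condition (all real parts negative) and is
reported alongside.

Two Jacobian modes are available.  ``mode="correct"`` differentiates the
right-hand side exactly (a/(s+x) terms give a*s/(s+x)^2; the probiotic
recruitment delta*P*C/(b+P) has P-derivative delta*b*C/(b+P)^2); it is the
default and is validated against central finite differences.
``mode="paper_verbatim"`` reproduces the linearization as printed in the
source literature, which differs at a handful of entries (squared saturation
constants without the numerator factor, spurious ``(1-T*)`` and ``(1-P*)``
factors); it is retained for documented comparison only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import ModelParameters, _as_state_array
from .equilibria import EquilibriumReport, cd4_denominator

__all__ = [
    "StabilityReport",
    "jacobian",
    "eigenvalues",
    "block_characteristic_coeffs",
    "hurwitz_determinants",
    "matignon_classify",
    "assess_equilibrium",
]

MARGINAL_TOL = 1e-8


def jacobian(params: ModelParameters, state, mode: str = "correct",
             variant: str = "base") -> np.ndarray:
    """5x5 Jacobian of the right-hand side at ``state``."""
    T, M, G, C, P = _as_state_array(state)
    p = params
    J = np.zeros((5, 5))
    if mode == "correct":
        J[0, 0] = (p.g1 * (1.0 - 2.0 * T / p.s1)
                   - p.beta1 * M * p.s2 / (p.s2 + T) ** 2
                   - p.omega * C * p.s4 / (p.s4 + T) ** 2
                   - p.u3)
        J[0, 1] = -p.beta1 * T / (p.s2 + T)
        J[0, 3] = -p.omega * T / (p.s4 + T)
        J[1, 0] = p.g2 * p.s2 / (p.s2 + T) ** 2
        J[1, 1] = -(p.beta2 + p.d1)
        J[2, 0] = p.g3 * p.s3 / (p.s3 + T) ** 2
        J[2, 2] = -(p.beta3 + p.d2)
        J[3, 2] = p.g4
        J[3, 3] = -(p.beta4 + p.d3) + p.u2 + p.delta * P / (p.b + P)
        J[3, 4] = p.delta * p.b * C / (p.b + P) ** 2
        J[4, 4] = -p.vartheta
        if variant == "extended":
            J[1, 3] += p.g5 * p.s2 / (p.s2 + C) ** 2
            J[2, 1] += p.g6 * p.s3 / (p.s3 + M) ** 2
            J[2, 3] += p.g7 * p.s3 / (p.s3 + C) ** 2
        elif variant != "base":
            raise ValueError(f"unknown variant {variant!r}")
    elif mode == "paper_verbatim":
        if variant != "base":
            raise ValueError("paper_verbatim mode is only printed for the "
                             "base model")
        J[0, 0] = (p.g1 - p.u3 - 2.0 * p.g1 * T / p.s1
                   - p.beta1 * M * (1.0 - T) / (p.s2 + T) ** 2
                   - p.omega * C * (1.0 - T) / (p.s4 + T) ** 2)
        J[0, 1] = -p.beta1 * T / (p.s2 + T)
        J[0, 3] = -p.omega * T / (p.s4 + T)
        J[1, 0] = p.g2 * (1.0 - T) / (p.s2 + T) ** 2
        J[1, 1] = -(p.beta2 + p.d1)
        J[2, 0] = p.g3 * (1.0 - T) / (p.s3 + T) ** 2
        J[2, 2] = -(p.beta3 + p.d2)
        J[3, 2] = p.g4
        J[3, 3] = -(p.beta4 + p.d3) + p.u2 + p.delta * P / (p.b + P)
        J[3, 4] = p.delta * C * (1.0 - P) / (p.b + P) ** 2
        J[4, 4] = -p.vartheta
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return J


def eigenvalues(jac: np.ndarray) -> np.ndarray:
    """Spectrum of the linearization (5 complex numbers)."""
    jac = np.asarray(jac, dtype=float)
    if not np.all(np.isfinite(jac)):
        raise ValueError("Jacobian contains non-finite entries")
    return np.linalg.eigvals(jac)


def block_characteristic_coeffs(jac: np.ndarray) -> tuple[float, float, float, float]:
    """(R1, R2, R3, R4) of the (T, M, G, C) block quartic.

    The quartic is ``lambda^4 - R1 l^3 + R2 l^2 + R3 l + R4``; the returned
    coefficients equal the monic characteristic-polynomial coefficients of
    the 4x4 block with signs (-R1, R2, R3, R4).
    """
    A = np.asarray(jac, dtype=float)
    a1, a2, a3 = A[0, 0], A[0, 1], A[0, 3]
    a4, a5 = A[1, 0], A[1, 1]
    a6, a7, a8 = A[2, 0], A[2, 2], A[3, 2]
    a9 = A[3, 3]
    r1 = a1 + a5 + a7 + a9
    r2 = (a1 * a5 + a7 * a1 + a7 * a5 + a9 * a1 + a9 * a5 + a7 * a9
          - a2 * a4)
    r3 = (-a7 * a1 * a5 - a9 * a1 * a5 - a7 * a9 * a1 - a7 * a9 * a5
          + a2 * a4 * (a7 + a9) - a3 * a6 * a8)
    r4 = a7 * a9 * a1 * a5 - a2 * a4 * a7 * a9 + a3 * a6 * a8 * a5
    return float(r1), float(r2), float(r3), float(r4)


def hurwitz_determinants(R: Sequence[float]) -> tuple[float, float, float, float]:
    """Hurwitz determinants H1..H4 of the block quartic."""
    r1, r2, r3, r4 = (float(x) for x in R)
    h1 = -r1
    h2 = -r1 * r2 - r3
    h3 = -r1 * r2 * r3 - r1 ** 2 * r4 - r3 ** 2
    h4 = r4 * h3
    return h1, h2, h3, h4


def matignon_classify(eigs, alpha: float,
                      tol: float = MARGINAL_TOL) -> tuple[str, float]:
    """Fractional stability classification and margin.

    Stable iff every eigenvalue satisfies ``|arg(lambda)| > alpha*pi/2``
    strictly beyond ``tol``; eigenvalues within ``tol`` of the critical
    sector boundary (including lambda = 0) classify as marginal.  Returns
    ``(classification, margin)`` with margin = min |arg l| - alpha*pi/2.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    eigs = np.atleast_1d(np.asarray(eigs, dtype=complex))
    args = np.abs(np.angle(eigs))
    # arg(0) is 0 in numpy; a zero eigenvalue is marginal, handle via margin
    margin = float(np.min(args) - alpha * np.pi / 2.0)
    zero = np.any(np.abs(eigs) <= tol)
    if zero or abs(margin) <= tol:
        return "marginal", margin
    return ("stable" if margin > 0 else "unstable"), margin


@dataclass
class StabilityReport:
    """Linearization, spectrum, Hurwitz data and classification."""

    jacobian: np.ndarray
    eigenvalues: np.ndarray
    block_coeffs: tuple[float, float, float, float]
    hurwitz: tuple[float, float, float, float]
    theorem_conditions: dict
    matignon_margin: float
    classification: str
    alpha: float
    jacobian_mode: str = "correct"

    @property
    def hurwitz_all_positive(self) -> bool:
        return all(h > 0 for h in self.hurwitz)

    def to_json(self) -> str:
        return json.dumps({
            "jacobian": self.jacobian.tolist(),
            "eigenvalues_re": np.real(self.eigenvalues).tolist(),
            "eigenvalues_im": np.imag(self.eigenvalues).tolist(),
            "block_coeffs": list(self.block_coeffs),
            "hurwitz": list(self.hurwitz),
            "theorem_conditions": {k: bool(v) for k, v in
                                   self.theorem_conditions.items()},
            "matignon_margin": self.matignon_margin,
            "classification": self.classification,
            "alpha": self.alpha,
            "jacobian_mode": self.jacobian_mode,
        })


def assess_equilibrium(params: ModelParameters,
                       equilibrium: EquilibriumReport,
                       alpha: float,
                       mode: str = "correct",
                       variant: str = "base") -> StabilityReport:
    """Full stability report at an equilibrium.

    For the tumor-free equilibrium the named theorem conditions are the
    negativity of the tumor eigenvalue (lambda4 = g1 - u3 - omega*C*/s4,
    correct mode) and of the CD4 eigenvalue (lambda5 = -D_C); for a
    coexistence equilibrium they are the four Hurwitz positivity conditions.
    """
    if not equilibrium.exists:
        raise ValueError("equilibrium does not exist; nothing to assess")
    state = equilibrium.as_array()
    jac = jacobian(params, state, mode=mode, variant=variant)
    eigs = eigenvalues(jac)
    R = block_characteristic_coeffs(jac)
    H = hurwitz_determinants(R)

    if equilibrium.kind == "tumor_free":
        p = params
        c_star = state[3]
        if mode == "correct":
            lam4 = p.g1 - p.u3 - p.omega * c_star / p.s4
        else:
            lam4 = p.g1 - p.u3 - p.omega * c_star / p.s4 ** 2
        lam5 = -cd4_denominator(p)
        conds = {"lambda4_negative": lam4 < 0, "lambda5_negative": lam5 < 0}
    else:
        h1, h2, h3, h4 = H
        conds = {"H1_positive": h1 > 0, "H2_positive": h2 > 0,
                 "H3_positive": h3 > 0, "H4_positive": h4 > 0}

    classification, margin = matignon_classify(eigs, alpha)
    conds["hurwitz_matches_spectrum"] = (
        all(h > 0 for h in H)
        == bool(np.all(np.real(_block_spectrum(jac)) < 0)))

    return StabilityReport(
        jacobian=jac, eigenvalues=eigs, block_coeffs=R, hurwitz=H,
        theorem_conditions=conds, matignon_margin=margin,
        classification=classification, alpha=alpha, jacobian_mode=mode)


def _block_spectrum(jac: np.ndarray) -> np.ndarray:
    """Eigenvalues of the (T, M, G, C) block (P row decouples)."""
    idx = np.ix_([0, 1, 2, 3], [0, 1, 2, 3])
    return np.linalg.eigvals(np.asarray(jac, dtype=float)[idx])
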