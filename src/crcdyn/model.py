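"""Fractional-order colon-cancer dynamics under combination therapy.

The model couples five populations/concentrations

* ``T`` — tumor cells,
* ``M`` — macrophages,
* ``G`` — dendritic cells,
* ``C`` — CD4+ T helper cells,
* ``P`` — probiotic drug concentration,

through a Caputo fractional system ``D^alpha x = f(x)`` of order
``alpha in (0, 1]``.  Tumor cells grow logistically (rate ``g1``, carrying
capacity ``s1``) and are killed by macrophages (``beta1``), CD4+ T cells
(``omega``) and chemotherapy (``u3``).  Macrophages and dendritic cells are
recruited by the tumor through saturating (Michaelis–Menten) terms with
half-saturation constants ``s2``/``s3``; CD4+ cells are produced at base rate
``r2``, activated by dendritic cells (``g4``), boosted by immunotherapy
(``u2``) and recruited by the probiotic via ``delta*P*C/(b+P)``.  The
probiotic is dosed at constant rate ``u1`` and decays at rate ``vartheta``.

An extended variant adds three further cross-recruitment channels:
``g5`` (CD4+ -> macrophages), ``g6`` (macrophages -> dendritic cells) and
``g7`` (CD4+ -> dendritic cells); with ``g5=g6=g7=0`` it reduces exactly to
the base model.

To keep time dimensions consistent for fractional orders the right-hand side
carries a constant prefactor ``sigma**(1-alpha)`` (``sigma`` a time-rescaling
constant, default 1, at which the scaled and unscaled systems coincide).

Drug inputs ``u1, u2, u3`` are constant doses: every scenario studied uses
constant controls, so the system is autonomous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "STATE_NAMES",
    "ModelParameters",
    "FractionalConfig",
    "StateVector",
    "default_parameters",
    "rhs_base",
    "rhs_extended",
    "scaled_rhs",
    "params_to_dict",
    "params_from_dict",
    "save_config",
    "load_config",
]

#: order of state components everywhere in the package
STATE_NAMES = ("T", "M", "G", "C", "P")

#: literature ranges for the parameters that are given as intervals rather
#: than point values; draws/validation warn outside these.
PARAMETER_RANGES = {
    "g1": (0.1, 0.9),
    "g2": (0.2, 0.9),
    "g3": (0.2, 0.9),
    "g4": (0.1, 0.9),
    "delta": (0.15, 0.60),
}

_POSITIVE_FIELDS = ("s1", "s2", "s3", "s4", "b", "vartheta")


@dataclass(frozen=True)
class ModelParameters:
    """All rate, saturation and dose constants of the model.

    Defaults reproduce the fixed literature values (saturation constants,
    production/death rates, chemo kill rates, probiotic decay) together with
    the baseline choices for the interval-valued parameters used throughout
    the worked applications.  ``g5``, ``g6``, ``g7`` default to 0, i.e. the
    base model.
    """

    g1: float = 0.1        # tumor intrinsic growth rate (1/time)
    s1: float = 1000.0     # tumor carrying capacity (cells)
    s2: float = 50.0       # half-saturation, macrophage terms (cells)
    s3: float = 50.0       # half-saturation, dendritic terms (cells)
    s4: float = 50.0       # half-saturation, CD4 kill term (cells)
    r1: float = 0.3        # dendritic production rate (cells/time)
    r2: float = 0.7        # CD4 production rate (cells/time)
    beta1: float = 0.1     # macrophage tumor-kill rate (1/time)
    omega: float = 0.3     # CD4 tumor-kill rate (1/time)
    g2: float = 0.2        # macrophage recruitment rate by tumor
    beta2: float = 0.5     # macrophage death rate
    g3: float = 0.3        # dendritic recruitment rate by tumor
    beta3: float = 0.4     # dendritic death rate
    g4: float = 0.1        # CD4 activation rate by dendritic cells
    beta4: float = 0.7     # CD4 death rate
    d1: float = 0.008      # chemo-induced macrophage death rate
    d2: float = 0.0008     # chemo-induced dendritic death rate
    d3: float = 0.0001     # chemo-induced CD4 death rate
    vartheta: float = 1.0  # probiotic decay rate (1/time)
    delta: float = 0.15    # CD4 recruitment rate by probiotic
    b: float = 0.25        # probiotic half-saturation (concentration)
    u1: float = 0.0        # probiotic dose rate
    u2: float = 0.0        # immunotherapy dose rate
    u3: float = 0.0        # chemotherapy dose rate
    g5: float = 0.0        # extended: CD4 -> macrophage recruitment
    g6: float = 0.0        # extended: macrophage -> dendritic recruitment
    g7: float = 0.0        # extended: CD4 -> dendritic recruitment

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not np.isfinite(value):
                raise ValueError(f"parameter {name} must be finite, got {value}")
            if value < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {value}")
        for name in _POSITIVE_FIELDS:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0")
        for name, (lo, hi) in PARAMETER_RANGES.items():
            value = getattr(self, name)
            if not lo <= value <= hi:
                warnings.warn(
                    f"parameter {name}={value} outside the literature range "
                    f"[{lo}, {hi}]",
                    stacklevel=2,
                )

    @property
    def is_extended(self) -> bool:
        return self.g5 > 0 or self.g6 > 0 or self.g7 > 0

    def with_doses(self, u1: float, u2: float, u3: float) -> "ModelParameters":
        return replace(self, u1=u1, u2=u2, u3=u3)

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class FractionalConfig:
    """Fractional order ``alpha`` and time-rescaling constant ``sigma``.

    ``alpha`` in (0, 1]; ``sigma > 0`` (default 1, where the dimensional
    rescaling disappears).  The effective right-hand-side prefactor is
    ``sigma**(1-alpha)``, identically 1 at ``alpha = 1``.
    """

    alpha: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @property
    def scale(self) -> float:
        """The prefactor ``sigma**(1-alpha)`` (exactly 1 at alpha=1)."""
        if self.alpha == 1.0:
            return 1.0
        return self.sigma ** (1.0 - self.alpha)


@dataclass(frozen=True)
class StateVector:
    """One (T, M, G, C, P) state; components finite and nonnegative."""

    T: float
    M: float
    G: float
    C: float
    P: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("state components must be finite")
        if np.any(arr < 0):
            raise ValueError("state components must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.T, self.M, self.G, self.C, self.P], dtype=float)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "StateVector":
        t, m, g, c, p = np.asarray(arr, dtype=float)
        return cls(t, m, g, c, p)


def default_parameters(**overrides: float) -> ModelParameters:
    """Parameter set with the fixed literature values; overrides applied on top."""
    return ModelParameters(**overrides)


def _as_state_array(state) -> np.ndarray:
    if isinstance(state, StateVector):
        return state.as_array()
    arr = np.asarray(state, dtype=float)
    if arr.shape != (5,):
        raise ValueError(f"state must have 5 components, got shape {arr.shape}")
    return arr


def rhs_base(state, params: ModelParameters) -> np.ndarray:
    """Right-hand side kernels (K1..K5) of the base model at one state."""
    T, M, G, C, P = _as_state_array(state)
    p = params
    dT = (
        p.g1 * T * (1.0 - T / p.s1)
        - p.beta1 * T * M / (p.s2 + T)
        - p.omega * T * C / (p.s4 + T)
        - p.u3 * T
    )
    dM = p.g2 * T / (p.s2 + T) - (p.beta2 + p.d1) * M
    dG = p.r1 + p.g3 * T / (p.s3 + T) - (p.beta3 + p.d2) * G
    dC = (
        p.r2
        + p.g4 * G
        - (p.beta4 + p.d3) * C
        + p.delta * P * C / (p.b + P)
        + p.u2 * C
    )
    dP = p.u1 - p.vartheta * P
    return np.array([dT, dM, dG, dC, dP])


def rhs_extended(state, params: ModelParameters) -> np.ndarray:
    """Extended-model kernels: adds CD4->M, M->G and CD4->G recruitment.

    With ``g5 = g6 = g7 = 0`` this returns ``rhs_base`` exactly.
    """
    arr = _as_state_array(state)
    _, M, _, C, _ = arr
    p = params
    out = rhs_base(arr, params)
    out[1] += p.g5 * C / (p.s2 + C)
    out[2] += p.g6 * M / (p.s3 + M) + p.g7 * C / (p.s3 + C)
    return out


def rhs_for_variant(variant: str):
    if variant == "base":
        return rhs_base
    if variant == "extended":
        return rhs_extended
    raise ValueError(f"unknown variant {variant!r} (expected 'base' or 'extended')")


def scaled_rhs(state, params: ModelParameters, config: FractionalConfig,
               variant: str = "base") -> np.ndarray:
    """``sigma**(1-alpha) * rhs`` — the field of ``D^alpha x = sigma^(1-a) f(x)``."""
    return config.scale * rhs_for_variant(variant)(state, params)


def make_field(params: ModelParameters, config: FractionalConfig,
               variant: str = "base"):
    """Closure ``x -> scaled_rhs(x, ...)`` suitable for the solver."""
    rhs = rhs_for_variant(variant)
    scale = config.scale

    def field(x: np.ndarray) -> np.ndarray:
        return scale * rhs(x, params)

    return field


# ---------------------------------------------------------------------------
# flat key-value config I/O

_CONFIG_EXTRA_KEYS = ("alpha", "sigma")


def params_to_dict(params: ModelParameters,
                   config: FractionalConfig | None = None) -> dict:
    out = {k: float(v) for k, v in asdict(params).items()}
    if config is not None:
        out["alpha"] = float(config.alpha)
        out["sigma"] = float(config.sigma)
    return out


def params_from_dict(data: Mapping[str, float]) -> tuple[ModelParameters, FractionalConfig]:
    extra = {k: float(data[k]) for k in _CONFIG_EXTRA_KEYS if k in data}
    fields = {k: float(v) for k, v in data.items() if k not in _CONFIG_EXTRA_KEYS}
    return ModelParameters(**fields), FractionalConfig(**extra)


def save_config(path, params: ModelParameters,
                config: FractionalConfig | None = None) -> None:
    """Write a flat ``key: value`` config file (YAML-compatible)."""
    data = params_to_dict(params, config)
    text = "\n".join(f"{k}: {data[k]!r}" for k in data) + "\n"
    Path(path).write_text(text)


def load_config(path) -> tuple[ModelParameters, FractionalConfig]:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} is not a flat key-value mapping")
    return params_from_dict(data)
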