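"""Three-state barnase folding / chaperone-binding equilibrium.

The biosensor's barnase kernel populates three states in cells without
aggregates: folded (N), free unfolded (U) and unfolded bound to chaperone
(UC).  Folding is fast relative to synthesis and degradation, so the
N/U ratio stays at the folding equilibrium constant K_f while chaperone
binding drains the unfolded pool.  Mass action gives, for fraction folded
f = [N]/B with total biosensor B and total latent chaperone C:

    C(f) = K_d * K_f * (1/f - 1 - 1/K_f) + B * (1 - f * (1 + 1/K_f))

which is strictly decreasing in f and zero at the chaperone-free
(intrinsic) fraction K_f/(1+K_f).  The change in latent chaperone between
treatment and control follows as

    dC = -K_d*K_f*(f_t - f_c)/(f_t*f_c) - B*(f_t - f_c)*(1 + 1/K_f)

Concentrations are in µM throughout; K_f is dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

#: Gas constant in kJ/(mol*K).
R_KJ = 8.314e-3

#: In-cell temperature (37 °C culture), kelvin.
T_CELL = 310.0
#: Denaturation-assay temperature (23 °C plate reader), kelvin.
T_ASSAY = 296.0

__all__ = [
    "R_KJ",
    "T_CELL",
    "T_ASSAY",
    "FoldingParams",
    "EquilibriumSystem",
    "EquilibriumState",
    "DeltaCInput",
    "kf_from_dg",
    "intrinsic_fraction_folded",
    "chaperone_for_fraction",
    "fraction_folded_closed_form",
    "solve_equilibrium",
    "delta_c",
]


@dataclass(frozen=True)
class FoldingParams:
    """Folding free energy and temperature defining K_f.

    dG_F is in kJ/mol, negative = stable; temperature in kelvin.
    """

    dG_F: float
    temperature: float = T_CELL

    def __post_init__(self) -> None:
        if not math.isfinite(self.dG_F):
            raise ValueError(f"dG_F must be finite, got {self.dG_F}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")


@dataclass(frozen=True)
class EquilibriumSystem:
    """Parameters of the three-state equilibrium.

    K_f : folded/free-unfolded equilibrium constant (dimensionless)
    K_d : chaperone-client dissociation constant, µM
    B : total biosensor (barnase) concentration, µM
    C_total : total latent chaperone concentration, µM
    """

    K_f: float
    K_d: float
    B: float
    C_total: float

    def __post_init__(self) -> None:
        if self.K_f <= 0:
            raise ValueError(f"K_f must be > 0, got {self.K_f}")
        if self.K_d <= 0:
            raise ValueError(f"K_d must be > 0, got {self.K_d}")
        if self.B <= 0:
            raise ValueError(f"B must be > 0, got {self.B}")
        if self.C_total < 0:
            raise ValueError(f"C_total must be >= 0, got {self.C_total}")


@dataclass(frozen=True)
class EquilibriumState:
    """Solved state: fraction folded and the four species concentrations (µM)."""

    f: float
    conc_folded: float
    conc_unfolded_free: float
    conc_unfolded_bound: float
    conc_chaperone_free: float


@dataclass(frozen=True)
class DeltaCInput:
    """Inputs for the latent-chaperone difference.

    f_c and f_t are fractions folded under control and treatment; both must
    lie in (0, K_f/(1+K_f)].
    """

    K_d: float
    K_f: float
    B: float
    f_c: float
    f_t: float

    def __post_init__(self) -> None:
        fmax = intrinsic_fraction_folded(self.K_f)
        for name, f in (("f_c", self.f_c), ("f_t", self.f_t)):
            if not 0 < f <= fmax * (1 + 1e-12):
                raise ValueError(
                    f"{name}={f} outside admissible interval (0, {fmax:.6g}]"
                )


def kf_from_dg(params: FoldingParams) -> float:
    """K_f = exp(-dG_F / (R*T)); returns ``inf`` when the exponent overflows."""
    x = -params.dG_F / (R_KJ * params.temperature)
    if x > 700.0:  # exp would overflow float64; K_f is effectively infinite
        return math.inf
    return math.exp(x)


def intrinsic_fraction_folded(K_f: float) -> float:
    """Chaperone-free fraction folded K_f/(1+K_f)."""
    if not K_f > 0:
        raise ValueError(f"K_f must be > 0, got {K_f}")
    if math.isinf(K_f):
        return 1.0
    return K_f / (1.0 + K_f)


def chaperone_for_fraction(K_f: float, K_d: float, B: float, f: float) -> float:
    """Total chaperone C that pins the fraction folded at ``f``.

    Inverse of the equilibrium: strictly decreasing in f, zero at the
    intrinsic fraction folded.  Raises if f is outside (0, K_f/(1+K_f)].
    """
    fmax = intrinsic_fraction_folded(K_f)
    if not 0 < f <= fmax * (1 + 1e-12):
        raise ValueError(f"f={f} outside admissible interval (0, {fmax:.6g}]")
    f = min(f, fmax)
    return K_d * K_f * (1.0 / f - 1.0 - 1.0 / K_f) + B * (1.0 - f * (1.0 + 1.0 / K_f))


def fraction_folded_closed_form(K_f, K_d, B, C_total):
    """Exact fraction folded from the quadratic root of the mass-action system.

    C(f) = C_total is quadratic in f:
        B*q*f**2 + (C_total + K_d*K_f*q - B)*f - K_d*K_f = 0,  q = 1 + 1/K_f
    with a single positive root.  Accepts array inputs (used per cell by the
    simulator); :func:`solve_equilibrium` is the independent scalar route.
    """
    import numpy as np

    K_f = np.asarray(K_f, dtype=float)
    q = 1.0 + 1.0 / K_f
    a = np.asarray(B, dtype=float) * q
    b = np.asarray(C_total, dtype=float) + K_d * K_f * q - B
    c = -K_d * K_f
    # numerically stable positive root (a > 0, c < 0)
    disc = np.sqrt(b * b - 4.0 * a * c)
    f = np.where(b >= 0, 2.0 * (-c) / (b + disc), (disc - b) / (2.0 * a))
    return np.minimum(f, K_f / (1.0 + K_f))


def solve_equilibrium(sys: EquilibriumSystem) -> EquilibriumState:
    """Solve the three-state equilibrium for the fraction folded.

    Finds the unique root of ``chaperone_for_fraction(f) = C_total`` on
    (0, K_f/(1+K_f)] by bracketed Brent iteration (relative tolerance 1e-12)
    and reconstructs all species concentrations.
    """
    fmax = intrinsic_fraction_folded(sys.K_f)
    if sys.C_total == 0.0:
        f = fmax
    else:
        def g(f: float) -> float:
            return chaperone_for_fraction(sys.K_f, sys.K_d, sys.B, f) - sys.C_total

        lo = fmax * 1e-18
        while g(lo) < 0:  # expand bracket toward 0 until C(lo) > C_total
            lo *= 1e-3
            if lo < 1e-300:
                raise ArithmeticError(
                    f"equilibrium bracket collapse: no root in (0, {fmax}]"
                )
        try:
            f = brentq(g, lo, fmax, xtol=1e-300, rtol=1e-15, maxiter=200)
        except Exception as exc:  # pragma: no cover - defensive
            raise ArithmeticError(
                f"equilibrium root-finding failed on bracket ({lo}, {fmax}]: {exc}"
            ) from exc
    conc_folded = f * sys.B
    conc_unfolded_free = conc_folded / sys.K_f
    conc_unfolded_bound = max(sys.B - conc_folded - conc_unfolded_free, 0.0)
    conc_chaperone_free = max(sys.C_total - conc_unfolded_bound, 0.0)
    return EquilibriumState(
        f=f,
        conc_folded=conc_folded,
        conc_unfolded_free=conc_unfolded_free,
        conc_unfolded_bound=conc_unfolded_bound,
        conc_chaperone_free=conc_chaperone_free,
    )


def delta_c(inp: DeltaCInput) -> float:
    """Change in latent chaperone concentration between treatment and control.

    Positive when the treatment leaves more chaperone free to hold unfolded
    client (f_t < f_c).  Equals ``chaperone_for_fraction(f_t) -
    chaperone_for_fraction(f_c)`` algebraically.
    """
    df = inp.f_t - inp.f_c
    return (
        -inp.K_d * inp.K_f * df / (inp.f_t * inp.f_c)
        - inp.B * df * (1.0 + 1.0 / inp.K_f)
    )
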