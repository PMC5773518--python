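"""Global two-state urea-denaturation fitting of biosensor FRET curves.

Each mutant's relative FRET A/(D+A) versus urea [U] follows a two-state
unfolding model with linear pre- and post-transition baselines:

    FRET([U]) = [(a_N + b_N*[U]) + (a_D + b_D*[U]) * e^z] / (1 + e^z),
    z = -(m / RT) * (D50 - [U])

where D50 is the denaturation midpoint (M) and m the cooperativity
(kJ/(mol*M)), so that dG_F = m * D50.  Destabilised mutants are partially
unfolded at 0 M urea, so m and the four baseline parameters are shared
across the whole mutant panel and only D50 is mutant-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit
from scipy.special import expit

from .thermo import R_KJ, T_ASSAY

__all__ = [
    "DenaturationCurve",
    "GlobalFitResult",
    "relative_fret",
    "eval_two_state",
    "fit_global",
    "fit_replicates",
]


@dataclass(frozen=True)
class DenaturationCurve:
    """One mutant's urea series: strictly increasing urea (M) and FRET ratios."""

    mutant_id: str
    urea: np.ndarray
    fret: np.ndarray
    replicate: int = 0

    def __post_init__(self) -> None:
        urea = np.asarray(self.urea, dtype=float)
        fret = np.asarray(self.fret, dtype=float)
        object.__setattr__(self, "urea", urea)
        object.__setattr__(self, "fret", fret)
        if urea.shape != fret.shape or urea.ndim != 1:
            raise ValueError("urea and fret must be equal-length 1-d arrays")
        if urea.size < 8:
            raise ValueError(f"need >= 8 urea points, got {urea.size}")
        if np.any(np.diff(urea) <= 0):
            raise ValueError("urea concentrations must be strictly increasing")
        if np.any(urea < 0):
            raise ValueError("urea concentrations must be >= 0")


@dataclass
class GlobalFitResult:
    """Shared-parameter fit output.

    ``dG_F = m * D50`` by construction for every mutant.  Mutants whose
    curve never leaves a baseline are listed in ``unidentifiable`` and
    carry no D50.
    """

    m: float
    alpha_N: float
    beta_N: float
    alpha_D: float
    beta_D: float
    D50: dict[str, float]
    dG_F: dict[str, float]
    stderr: dict[str, float]
    residual_rms: float
    unidentifiable: list[str] = field(default_factory=list)


def relative_fret(donor_intensity, acceptor_intensity):
    """Relative FRET efficiency A/(D+A) from donor and acceptor readings."""
    d = np.asarray(donor_intensity, dtype=float)
    a = np.asarray(acceptor_intensity, dtype=float)
    total = d + a
    if np.any(total <= 0):
        raise ValueError("relative FRET undefined for zero total signal")
    out = a / total
    return float(out) if out.ndim == 0 else out


def eval_two_state(
    urea,
    m: float,
    D50: float,
    alpha_N: float,
    beta_N: float,
    alpha_D: float,
    beta_D: float,
    temperature: float = T_ASSAY,
):
    """Two-state unfolding curve with linear baselines, evaluated stably.

    Written as a logistic mixture of the native and denatured baselines so
    large exponents never overflow.
    """
    u = np.asarray(urea, dtype=float)
    z = -(m / (R_KJ * temperature)) * (D50 - u)
    w_den = expit(z)  # weight of the denatured baseline
    native = alpha_N + beta_N * u
    denatured = alpha_D + beta_D * u
    out = native * (1.0 - w_den) + denatured * w_den
    return float(out) if out.ndim == 0 else out


def _is_baseline_only(curve: DenaturationCurve, min_span: float = 0.08) -> bool:
    """A curve whose FRET never spans ``min_span`` has no visible transition."""
    return float(np.ptp(curve.fret)) < min_span


def _d50_seed(curve: DenaturationCurve) -> float:
    """Urea at the steepest local FRET drop (finite-difference slope minimum)."""
    slopes = np.diff(curve.fret) / np.diff(curve.urea)
    mid = 0.5 * (curve.urea[1:] + curve.urea[:-1])
    return float(mid[np.argmin(slopes)])


def fit_global(
    curves: list[DenaturationCurve],
    temperature: float = T_ASSAY,
    start: dict | None = None,
    shared_baselines: bool = True,
    min_transition_span: float = 0.08,
) -> GlobalFitResult:
    """Fit all curves simultaneously with shared {m, baselines}, free D50.

    Curves of the same mutant share a single D50.  Unweighted least squares
    (ratiometric readings carry no stated weights); deterministic given
    identical inputs and starting values.  Curves with no visible
    transition are flagged unidentifiable and contribute only to the
    native baseline.
    """
    if not curves:
        raise ValueError("no curves supplied")
    mutants = sorted({c.mutant_id for c in curves})
    baseline_only = {
        mid
        for mid in mutants
        if all(_is_baseline_only(c, min_transition_span) for c in curves if c.mutant_id == mid)
    }
    fit_mutants = [mid for mid in mutants if mid not in baseline_only]
    if len(fit_mutants) < 1:
        raise ValueError("no curve shows a visible transition; nothing to fit")

    start = dict(start or {})
    params = lmfit.Parameters()
    all_fret = np.concatenate([c.fret for c in curves])
    hi, lo = float(np.max(all_fret)), float(np.min(all_fret))
    params.add("m", value=start.get("m", 8.0), min=1e-3)
    params.add("alpha_N", value=start.get("alpha_N", hi))
    params.add("beta_N", value=start.get("beta_N", 0.0))
    params.add("alpha_D", value=start.get("alpha_D", lo))
    params.add("beta_D", value=start.get("beta_D", 0.0))
    keys: dict[str, str] = {}
    for i, mid in enumerate(fit_mutants):
        key = f"D50_{i}"
        keys[mid] = key
        # midpoint may extrapolate below 0 M for mutants mostly unfolded in water
        seeds = [_d50_seed(c) for c in curves if c.mutant_id == mid]
        params.add(key, value=start.get(f"D50:{mid}", float(np.mean(seeds))))
    if not shared_baselines:
        # per-mutant baselines, diagnostics only
        raise NotImplementedError("per-mutant baselines not implemented")

    def residuals(p: lmfit.Parameters) -> np.ndarray:
        res = []
        for c in curves:
            if c.mutant_id in baseline_only:
                res.append(c.fret - (p["alpha_N"].value + p["beta_N"].value * c.urea))
                continue
            model = eval_two_state(
                c.urea,
                p["m"].value,
                p[keys[c.mutant_id]].value,
                p["alpha_N"].value,
                p["beta_N"].value,
                p["alpha_D"].value,
                p["beta_D"].value,
                temperature,
            )
            res.append(c.fret - model)
        return np.concatenate(res)

    out = lmfit.minimize(residuals, params, method="leastsq", xtol=1e-12, ftol=1e-12)
    if not out.success:
        worst = _worst_mutant(curves, out.params, keys, baseline_only, temperature)
        raise RuntimeError(f"global denaturation fit failed to converge (worst: {worst})")

    m = float(out.params["m"].value)
    d50 = {mid: float(out.params[keys[mid]].value) for mid in fit_mutants}
    stderr = {}
    for mid in fit_mutants:
        se_d50 = out.params[keys[mid]].stderr
        se_m = out.params["m"].stderr
        if se_d50 is not None and se_m is not None:
            # var(m*D50) by first-order propagation, covariance ignored
            stderr[mid] = float(
                np.hypot(m * se_d50, d50[mid] * se_m)
            )
        else:
            stderr[mid] = float("nan")
    return GlobalFitResult(
        m=m,
        alpha_N=float(out.params["alpha_N"].value),
        beta_N=float(out.params["beta_N"].value),
        alpha_D=float(out.params["alpha_D"].value),
        beta_D=float(out.params["beta_D"].value),
        D50=d50,
        dG_F={mid: m * v for mid, v in d50.items()},
        stderr=stderr,
        residual_rms=float(np.sqrt(np.mean(out.residual**2))),
        unidentifiable=sorted(baseline_only),
    )


def _worst_mutant(curves, params, keys, baseline_only, temperature) -> str:
    worst, worst_ssr = "", -1.0
    for c in curves:
        if c.mutant_id in baseline_only:
            continue
        model = eval_two_state(
            c.urea, params["m"].value, params[keys[c.mutant_id]].value,
            params["alpha_N"].value, params["beta_N"].value,
            params["alpha_D"].value, params["beta_D"].value, temperature,
        )
        ssr = float(np.sum((c.fret - model) ** 2))
        if ssr > worst_ssr:
            worst, worst_ssr = c.mutant_id, ssr
    return worst


def fit_replicates(
    curves: list[DenaturationCurve],
    temperature: float = T_ASSAY,
    **kwargs,
) -> tuple[dict[str, float], dict[str, float], list[GlobalFitResult]]:
    """Fit each replicate set independently and average dG_F per mutant.

    Returns (mean dG_F, SD of dG_F across replicates, per-replicate fits).
    """
    reps = sorted({c.replicate for c in curves})
    fits = [
        fit_global([c for c in curves if c.replicate == r], temperature, **kwargs)
        for r in reps
    ]
    mutants = sorted({m for f in fits for m in f.dG_F})
    mean_dg, sd_dg = {}, {}
    for mid in mutants:
        vals = np.array([f.dG_F[mid] for f in fits if mid in f.dG_F])
        mean_dg[mid] = float(vals.mean())
        sd_dg[mid] = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    return mean_dg, sd_dg, fits
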