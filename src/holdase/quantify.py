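"""From Lower-slope gradients to fraction folded and latent-chaperone change.

The Lower-slope gradient is linear in the fraction of folded barnase
(soluble cells are a mixture of low-FRET unfolded and medium-FRET folded
biosensor), so a panel of mutants with known stabilities calibrates the
gradient scale: gradient = a * f + b, with f predicted from each mutant's
dG_F under the control condition.  Inverting the calibration for control
and treatment gradients gives f_c and f_t, which the three-state model
turns into the latent-chaperone difference ΔC.  AFU scales cancel in ΔC
because both gradients and the calibration share the instrument scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import thermo
from .classify import GatingConfig, acceptor_window, ClassifiedEvents, LABEL_LOWER
from .events import EventTable
from .stats import wilcoxon_signed_rank

__all__ = [
    "MutantSpec",
    "PanelCalibration",
    "DeltaCResult",
    "calibrate_slope_to_fraction",
    "estimate_B",
    "estimate_B_slope_weighted",
    "delta_c_per_mutant",
    "panel_delta_c",
]

#: Clipping margin for fractions at the admissible boundary.
F_EPS = 1e-6


@dataclass(frozen=True)
class MutantSpec:
    """A panel member: identifier, folding free energy, inclusion flag."""

    mutant_id: str
    dG_F: float
    include_in_deltaC: bool = True


@dataclass(frozen=True)
class PanelCalibration:
    """Affine map between fraction folded and Lower-slope gradient."""

    a: float  # gradient units per unit fraction folded
    b: float  # gradient offset (the fully-unfolded slope)
    residual_rms: float

    def gradient(self, f):
        return self.a * np.asarray(f) + self.b

    def fraction(self, gradient):
        """Inverse map, clipped into (F_EPS, 1]."""
        f = (np.asarray(gradient, dtype=float) - self.b) / self.a
        out = np.clip(f, F_EPS, 1.0)
        return float(out) if out.ndim == 0 else out


@dataclass
class DeltaCResult:
    """Panel-level holdase statistic."""

    per_mutant: dict[str, float]
    per_mutant_replicates: dict[str, list[float]]
    mean: float
    sem: float
    p_value: float
    K_d: float

    @property
    def mean_over_kd(self) -> float:
        """ΔC/K_d: the K_d-proportional part made unitless for transparency."""
        return self.mean / self.K_d


def calibrate_slope_to_fraction(
    gradients: dict[str, float],
    panel: list[MutantSpec],
    temperature: float = thermo.T_CELL,
) -> PanelCalibration:
    """Least-squares affine fit of control-condition gradients against the
    fraction folded predicted from each mutant's dG_F.

    Requires >= 4 mutants whose predicted fractions span >= 0.5 so the
    slope is identifiable.  A non-positive fitted scale means the donor and
    FRET channel assignment is inverted.
    """
    specs = {m.mutant_id: m for m in panel}
    mutants = [m for m in gradients if m in specs]
    if len(mutants) < 4:
        raise ValueError(f"need >= 4 panel mutants with gradients, got {len(mutants)}")
    f_pred = np.array(
        [
            thermo.intrinsic_fraction_folded(
                thermo.kf_from_dg(thermo.FoldingParams(specs[m].dG_F, temperature))
            )
            for m in mutants
        ]
    )
    if np.ptp(f_pred) < 0.5:
        raise ValueError(
            f"panel spans only {np.ptp(f_pred):.2f} in predicted fraction folded; "
            "need >= 0.5 for a stable calibration"
        )
    g = np.array([gradients[m] for m in mutants])
    A = np.column_stack([f_pred, np.ones_like(f_pred)])
    (a, b), res, *_ = np.linalg.lstsq(A, g, rcond=None)
    if a <= 0:
        raise ValueError(
            "fitted calibration scale is non-positive: donor/FRET channels "
            "appear inverted"
        )
    rms = float(np.sqrt(res[0] / len(g))) if res.size else 0.0
    return PanelCalibration(a=float(a), b=float(b), residual_rms=rms)


def estimate_B(
    events: EventTable,
    afu_to_uM: float,
    cfg: GatingConfig = GatingConfig(),
    classified: ClassifiedEvents | None = None,
) -> float:
    """Biosensor concentration B (µM): geometric mean of acceptor intensity
    in the Lower-slope analysis window, scaled by the AFU→µM factor."""
    if not afu_to_uM > 0:
        raise ValueError("afu_to_uM conversion factor must be > 0")
    lo, hi = acceptor_window(events, cfg)
    mask = (events.acceptor >= lo) & (events.acceptor <= hi)
    if classified is not None:
        mask &= classified.labels == LABEL_LOWER
    acc = events.acceptor[mask]
    acc = acc[acc > 0]
    if acc.size == 0:
        raise ValueError("no events in the acceptor analysis window")
    return float(np.exp(np.mean(np.log(acc))) * afu_to_uM)


def estimate_B_slope_weighted(
    events: EventTable,
    afu_to_uM: float,
    cfg: GatingConfig = GatingConfig(),
    classified: ClassifiedEvents | None = None,
) -> tuple[float, float]:
    """Donor²-weighted mean biosensor concentration in the analysis window.

    The origin-constrained slope fit weights each cell by its squared donor
    intensity, so the gradient-derived fraction folded is a donor²-weighted
    cell average; the matching effective B uses the same weights, which
    keeps the scalar ΔC expression consistent with the per-cell mixture.
    Returns (B in µM, total weight).
    """
    if not afu_to_uM > 0:
        raise ValueError("afu_to_uM conversion factor must be > 0")
    lo, hi = acceptor_window(events, cfg)
    mask = (events.acceptor >= lo) & (events.acceptor <= hi)
    if classified is not None:
        mask &= classified.labels == LABEL_LOWER
    if mask.sum() == 0:
        raise ValueError("no events in the acceptor analysis window")
    w = events.donor[mask] ** 2
    return (
        float(np.sum(w * events.acceptor[mask]) / np.sum(w) * afu_to_uM),
        float(np.sum(w)),
    )


def delta_c_per_mutant(
    g_control: float,
    g_treatment: float,
    cal: PanelCalibration,
    spec: MutantSpec,
    K_d: float,
    B: float,
    temperature: float = thermo.T_CELL,
) -> float:
    """ΔC (µM) for one mutant from matched control/treatment gradients.

    Gradients are inverted through the panel calibration; fractions landing
    outside (0, K_f/(1+K_f)] are clipped to the boundary (margin 1e-6).
    """
    K_f = thermo.kf_from_dg(thermo.FoldingParams(spec.dG_F, temperature))
    f_max = thermo.intrinsic_fraction_folded(K_f)
    f_c = float(np.clip(cal.fraction(g_control), F_EPS, f_max))
    f_t = float(np.clip(cal.fraction(g_treatment), F_EPS, f_max))
    return thermo.delta_c(thermo.DeltaCInput(K_d=K_d, K_f=K_f, B=B, f_c=f_c, f_t=f_t))


def panel_delta_c(
    per_mutant: dict[str, list[float] | float],
    included: list[str] | None = None,
    K_d: float = float("nan"),
    point_estimates: dict[str, float] | None = None,
) -> DeltaCResult:
    """Panel summary: mean ± SEM across mutants and an exact two-sided
    Wilcoxon signed-rank test of the per-mutant ΔC values against zero.

    ``per_mutant`` holds per-replicate values (or scalars); the mutant
    point estimate defaults to the replicate mean unless
    ``point_estimates`` supplies one (e.g. from replicate-mean gradients).
    """
    reps = {
        m: list(np.atleast_1d(v).astype(float))
        for m, v in per_mutant.items()
        if included is None or m in included
    }
    if len(reps) < 6:
        raise ValueError(f"need >= 6 included mutants, got {len(reps)}")
    means = {
        m: float(point_estimates[m]) if point_estimates else float(np.mean(v))
        for m, v in reps.items()
    }
    vals = np.array(list(means.values()))
    if np.all(vals == 0):
        warnings.warn("all per-mutant ΔC values are zero; p set to 1")
        p = 1.0
    else:
        p = wilcoxon_signed_rank(vals)
    return DeltaCResult(
        per_mutant=means,
        per_mutant_replicates=reps,
        mean=float(vals.mean()),
        sem=float(vals.std(ddof=1) / np.sqrt(vals.size)),
        p_value=p,
        K_d=K_d,
    )
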