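"""Expression-binned aggregation analysis: A50% and its treatment offset.

The proportion of cells whose biosensor has aggregated rises sigmoidally
with expression level.  Cells are binned by acceptor (Venus) fluorescence
into 9 logarithmic bins, the percent of Upper-slope cells per bin is fit
with a Boltzmann sigmoid (plateaus fixed at 0 and 100), and A50% — the
expression at which half the cells contain aggregates — is read off the
midpoint.  Across a mutant panel log10(A50%) is linear in dG_F; a
treatment that changes proteostasis shifts this line vertically, and that
translational offset (ΔA50%) is a single scalar measure of the change in
aggregation propensity, tested by an extra-sum-of-squares F-test
(shared vs per-condition slopes) and a Wilcoxon signed-rank test on the
per-mutant offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import f as f_dist

from .classify import ClassifiedEvents, LABEL_LOWER
from .events import EventTable
from .stats import wilcoxon_signed_rank

__all__ = [
    "ExpressionBins",
    "BoltzmannFit",
    "A50Landscape",
    "SharedSlopeRegression",
    "LowAggregationError",
    "bin_events",
    "fit_boltzmann",
    "shared_slope_regression",
]

DEFAULT_LOG10_BOUNDS = (2.5, 4.5)


class LowAggregationError(ValueError):
    """Raised when a mutant aggregates too little for a meaningful A50% fit."""


@dataclass
class ExpressionBins:
    """Aggregation prevalence per logarithmic expression bin.

    ``midpoints`` are in log10 AFU, evenly spaced; bins are half-open on
    the edges ([lo, hi), ties to the higher bin).  ``usable`` marks bins
    with at least ``min_cells`` cells.
    """

    midpoints: np.ndarray
    edges: np.ndarray
    counts: np.ndarray
    percent_upper: np.ndarray
    usable: np.ndarray
    n_out_of_bounds: int


@dataclass(frozen=True)
class BoltzmannFit:
    """Sigmoid fit of percent aggregated vs log10 expression.

    Plateaus are fixed at 0 and 100 so the midpoint x50 is both the
    half-maximal and the 50%-absolute aggregation point; A50 = 10**x50.
    """

    x50: float
    width: float
    x50_se: float
    bottom: float = 0.0
    top: float = 100.0

    @property
    def A50(self) -> float:
        return 10.0**self.x50


@dataclass
class A50Landscape:
    """Per mutant x condition replicate A50 values (log10 AFU) and exclusions."""

    x50: dict[tuple[str, str], list[float]] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def add(self, mutant: str, condition: str, x50: float) -> None:
        self.x50.setdefault((mutant, condition), []).append(x50)

    def mean_x50(self, mutant: str, condition: str) -> float:
        return float(np.mean(self.x50[(mutant, condition)]))

    def mutants(self, conditions) -> list[str]:
        return sorted(
            {
                m
                for (m, c) in self.x50
                if m not in self.excluded
                and all((m, cond) in self.x50 for cond in conditions)
            }
        )


@dataclass
class SharedSlopeRegression:
    """Joint regression of log10(A50) on dG_F with a common slope."""

    slope: float
    intercept_control: float
    intercept_treatment: float
    deltaA50_offset: float  # log10 AFU, treatment minus control
    f_test_p: float
    separate_slopes: tuple[float, float]
    per_mutant_delta: dict[str, float]
    wilcoxon_p: float


def boltzmann(x, x50, width, bottom=0.0, top=100.0):
    """Boltzmann sigmoid rising with x (aggregation increases with expression)."""
    return bottom + (top - bottom) / (1.0 + np.exp((x50 - np.asarray(x)) / width))


def bin_events(
    classified: ClassifiedEvents,
    events: EventTable,
    bounds: tuple[float, float] = DEFAULT_LOG10_BOUNDS,
    n_bins: int = 9,
    min_cells: int = 20,
) -> ExpressionBins:
    """Bin cells by log10 acceptor intensity and tabulate percent aggregated.

    The ``n_bins`` midpoints evenly span ``bounds`` (defaults give
    10^2.5 ... 10^4.5 spaced 0.25); edges sit halfway between midpoints.
    Every transfected (lower or upper) cell inside the edges is counted.
    """
    lo, hi = bounds
    if hi - lo < 1.0:
        raise ValueError("bin bounds must span at least one decade")
    midpoints = np.linspace(lo, hi, n_bins)
    step = midpoints[1] - midpoints[0]
    edges = np.concatenate([midpoints - step / 2, [midpoints[-1] + step / 2]])
    logx = np.log10(events.acceptor, where=events.acceptor > 0,
                    out=np.full(len(events), -np.inf))
    # np.digitize with right=False: edge values go to the higher bin
    idx = np.digitize(logx, edges) - 1
    in_bounds = (idx >= 0) & (idx < n_bins)
    is_upper = classified.labels != LABEL_LOWER
    counts = np.bincount(idx[in_bounds], minlength=n_bins)
    upper_counts = np.bincount(idx[in_bounds & is_upper], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        percent = np.where(counts > 0, 100.0 * upper_counts / np.maximum(counts, 1), np.nan)
    usable = counts >= min_cells
    if not usable.any():
        raise ValueError("no expression bin reaches the minimum cell count")
    return ExpressionBins(
        midpoints=midpoints,
        edges=edges,
        counts=counts,
        percent_upper=percent,
        usable=usable,
        n_out_of_bounds=int((~in_bounds).sum()),
    )


def fit_boltzmann(
    bins: ExpressionBins,
    low_aggregation_threshold: float = 20.0,
    min_bins: int = 4,
    min_spread: float = 20.0,
) -> BoltzmannFit:
    """Count-weighted Boltzmann fit of percent aggregated vs log10 midpoint.

    Mutants whose aggregation never reaches ``low_aggregation_threshold``
    percent in any usable bin are flagged low-aggregators
    (:class:`LowAggregationError`) and excluded downstream: their midpoint
    lies beyond the measured range and the fit is badly conditioned.
    """
    x = bins.midpoints[bins.usable]
    y = bins.percent_upper[bins.usable]
    w = bins.counts[bins.usable].astype(float)
    if x.size < min_bins:
        raise ValueError(f"only {x.size} usable bins, need >= {min_bins}")
    if np.nanmax(y) < low_aggregation_threshold:
        raise LowAggregationError(
            f"max bin aggregation {np.nanmax(y):.1f}% below "
            f"{low_aggregation_threshold}%: low-aggregator"
        )
    if np.ptp(y) < min_spread:
        raise LowAggregationError(
            f"aggregation spread {np.ptp(y):.1f} points below {min_spread}"
        )
    x50_0 = float(np.interp(50.0, y, x)) if y[-1] > y[0] else float(x[len(x) // 2])
    popt, pcov = curve_fit(
        boltzmann,
        x,
        y,
        p0=[x50_0, 0.2],
        sigma=1.0 / np.sqrt(w),
        absolute_sigma=False,
        bounds=([x.min() - 2.0, 1e-3], [x.max() + 2.0, 2.0]),
        maxfev=20000,
    )
    return BoltzmannFit(
        x50=float(popt[0]), width=float(popt[1]), x50_se=float(np.sqrt(pcov[0, 0]))
    )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ssr = float(np.sum((y - X @ beta) ** 2))
    return beta, ssr


def shared_slope_regression(
    landscape: A50Landscape,
    panel_dG: dict[str, float],
    control: str,
    treatment: str,
) -> SharedSlopeRegression:
    """Common-slope regression of log10(A50) on dG_F for two conditions.

    The shared model fits one slope with per-condition intercepts; its
    intercept difference is the translational offset ΔA50% (log10 AFU).
    An extra-sum-of-squares F-test compares it against per-condition
    slopes.  Per-mutant offsets (treatment minus control of the
    replicate-mean log10 A50) feed a Wilcoxon signed-rank test.
    """
    mutants = [m for m in landscape.mutants([control, treatment]) if m in panel_dG]
    if len(mutants) < 4:
        raise ValueError(f"need >= 4 mutants with A50 in both conditions, got {len(mutants)}")
    dg = np.array([panel_dG[m] for m in mutants])
    y_c = np.array([landscape.mean_x50(m, control) for m in mutants])
    y_t = np.array([landscape.mean_x50(m, treatment) for m in mutants])
    y = np.concatenate([y_c, y_t])
    x = np.concatenate([dg, dg])
    is_t = np.concatenate([np.zeros_like(dg), np.ones_like(dg)])

    X_shared = np.column_stack([x, 1.0 - is_t, is_t])
    beta_s, ssr_s = _ols(X_shared, y)
    X_sep = np.column_stack([x * (1 - is_t), x * is_t, 1.0 - is_t, is_t])
    beta_f, ssr_f = _ols(X_sep, y)

    n, p_s, p_f = y.size, 3, 4
    if n <= p_f or ssr_f <= 0:
        raise ValueError("too few mutants for the slope comparison (rank deficient)")
    F = (ssr_s - ssr_f) / (p_f - p_s) / (ssr_f / (n - p_f))
    p_F = float(f_dist.sf(max(F, 0.0), p_f - p_s, n - p_f))

    per_mutant = {m: float(t - c) for m, c, t in zip(mutants, y_c, y_t)}
    deltas = np.array(list(per_mutant.values()))
    wilk = 1.0 if np.all(deltas == 0) else wilcoxon_signed_rank(deltas)
    return SharedSlopeRegression(
        slope=float(beta_s[0]),
        intercept_control=float(beta_s[1]),
        intercept_treatment=float(beta_s[2]),
        deltaA50_offset=float(beta_s[2] - beta_s[1]),
        f_test_p=p_F,
        separate_slopes=(float(beta_f[0]), float(beta_f[1])),
        per_mutant_delta=per_mutant,
        wilcoxon_p=float(wilk),
    )
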