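"""Classification of cells into Lower-slope (soluble) and Upper-slope
(aggregated) FRET populations, and extraction of the Lower-slope gradient.

On a FRET-vs-donor plot, cells with soluble biosensor fall on a line
through the origin whose gradient is proportional to FRET efficiency and
hence to the balance of folded and unfolded barnase; cells with aggregated
biosensor sit on a distinctly steeper line.  Because the Lower-slope
gradient differs per mutant, no fixed gate separates the populations;
instead the Lower slope is fitted robustly with iterative one-sided
outlier rejection, using wild-type* cells (which never aggregate) to set
the expected scatter around the line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EventTable

__all__ = [
    "GatingConfig",
    "SlopeFit",
    "ClassifiedEvents",
    "pregate_high_fret",
    "wt_residual_sd",
    "robust_origin_slope",
    "iterative_slope_fit",
    "classify",
    "lower_slope_gradient",
    "classify_sample",
]

LABEL_LOWER = "lower"
LABEL_UPPER = "upper"
LABEL_PREGATED = "pregated_high"


@dataclass(frozen=True)
class GatingConfig:
    """Gating parameters.

    sd_multiplier : threshold above the Lower slope, in wild-type* residual SDs
    n_iterations : outer fit/exclude iterations
    acceptor_range_fraction : width of the acceptor analysis window as a
        fraction of the instrument dynamic range
    acceptor_bounds : explicit (lo, hi) AFU window overriding the fraction
    instrument_max_afu : full-scale acceptor intensity defining the dynamic range
    min_events : minimum events for any fit
    """

    sd_multiplier: float = 2.0
    n_iterations: int = 4
    acceptor_range_fraction: float = 0.2
    acceptor_bounds: tuple[float, float] | None = None
    instrument_max_afu: float = 10**4.5
    min_events: int = 200

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be > 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < self.acceptor_range_fraction <= 1:
            raise ValueError("acceptor_range_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SlopeFit:
    gradient: float
    wt_residual_sd: float
    kept_fraction: float
    iterations_run: int


@dataclass
class ClassifiedEvents:
    """Per-event labels ('lower' / 'upper' / 'pregated_high') for one sample."""

    labels: np.ndarray
    slope_fit: SlopeFit

    @property
    def percent_upper(self) -> float:
        """Percent of all transfected events in the Upper-slope population,
        pre-gated very-high-FRET cells included."""
        upper = np.isin(self.labels, (LABEL_UPPER, LABEL_PREGATED))
        return 100.0 * float(upper.mean())


def pregate_high_fret(events: EventTable, wt_reference: EventTable) -> np.ndarray:
    """Mark cells with higher FRET/donor ratio than every wild-type* cell.

    Returns a boolean mask of pre-gated (very high FRET) events; these are
    excluded from slope fitting and later counted as Upper-slope.
    """
    if len(wt_reference) == 0:
        raise ValueError("wild-type* reference sample is empty")
    wt_max = float(np.max(wt_reference.fret / wt_reference.donor))
    return (events.fret / events.donor) > wt_max


def wt_residual_sd(wt_events: EventTable, gradient: float) -> float:
    """SD of wild-type* vertical residuals around the Lower slope (AFU)."""
    resid = wt_events.fret - gradient * wt_events.donor
    return float(np.std(resid, ddof=1))


def robust_origin_slope(
    donor: np.ndarray,
    fret: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-12,
) -> float:
    """Robust line through the origin by IRLS with Tukey bisquare weights."""
    x, y = donor, fret
    slope = float(np.dot(x, y) / np.dot(x, x))
    c = 4.685
    for _ in range(max_iter):
        r = y - slope * x
        scale = np.median(np.abs(r - np.median(r))) / 0.6744897501960817
        if scale <= 1e-12 * max(1.0, abs(slope) * float(np.median(x))):
            break  # effectively collinear
        u = r / (c * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0)
        denom = float(np.dot(w * x, x))
        if denom <= 0:
            break
        new = float(np.dot(w * x, y) / denom)
        if abs(new - slope) <= tol * max(1.0, abs(slope)):
            slope = new
            break
        slope = new
    return slope


def iterative_slope_fit(
    events: EventTable,
    cfg: GatingConfig,
    wt_sd: float,
    retained: np.ndarray | None = None,
) -> SlopeFit:
    """Fit the Lower-slope gradient with iterative one-sided rejection.

    Each of ``cfg.n_iterations`` rounds robust-fits a line through the
    origin on the currently included events, then drops events more than
    ``cfg.sd_multiplier * wt_sd`` *above* the line (cells below are kept;
    only aggregation pushes FRET up).  Deterministic.
    """
    include = np.ones(len(events), bool) if retained is None else retained.copy()
    if include.sum() < cfg.min_events:
        raise ValueError(
            f"sample {events.sample_id!r}: {include.sum()} events retained, "
            f"need >= {cfg.min_events}"
        )
    slope = 0.0
    for it in range(cfg.n_iterations):
        slope = robust_origin_slope(events.donor[include], events.fret[include])
        resid = events.fret - slope * events.donor
        include &= ~(resid > cfg.sd_multiplier * wt_sd)
        if include.sum() < cfg.min_events:
            raise ValueError(
                f"sample {events.sample_id!r}: fewer than {cfg.min_events} "
                f"events left after iteration {it + 1}"
            )
    n0 = len(events) if retained is None else int(retained.sum())
    return SlopeFit(
        gradient=slope,
        wt_residual_sd=wt_sd,
        kept_fraction=float(include.sum()) / n0,
        iterations_run=cfg.n_iterations,
    )


def classify(
    events: EventTable,
    slope_fit: SlopeFit,
    cfg: GatingConfig,
    wt_sd: float,
    pregated: np.ndarray | None = None,
) -> ClassifiedEvents:
    """Label every event lower / upper / pregated_high.

    An event is Upper when its FRET lies strictly above
    ``gradient*donor + sd_multiplier*wt_sd``; events exactly on the
    boundary stay Lower.
    """
    threshold = slope_fit.gradient * events.donor + cfg.sd_multiplier * wt_sd
    labels = np.where(events.fret > threshold, LABEL_UPPER, LABEL_LOWER)
    if pregated is not None:
        labels = np.where(pregated, LABEL_PREGATED, labels)
    return ClassifiedEvents(labels=labels, slope_fit=slope_fit)


def acceptor_window(events: EventTable, cfg: GatingConfig) -> tuple[float, float]:
    """Acceptor analysis window: explicit bounds, or the lowest-expression
    slice covering ``acceptor_range_fraction`` of the instrument dynamic range."""
    if cfg.acceptor_bounds is not None:
        return cfg.acceptor_bounds
    lo = float(np.min(events.acceptor))
    return lo, lo + cfg.acceptor_range_fraction * cfg.instrument_max_afu


def lower_slope_gradient(
    classified: ClassifiedEvents,
    events: EventTable,
    cfg: GatingConfig,
) -> float:
    """Reported per-sample gradient: origin-constrained robust fit on
    Lower-slope cells inside the acceptor analysis window.

    The low-expression window is where chaperone engagement is most
    pronounced and background still negligible.
    """
    lo, hi = acceptor_window(events, cfg)
    mask = (
        (classified.labels == LABEL_LOWER)
        & (events.acceptor >= lo)
        & (events.acceptor <= hi)
    )
    if mask.sum() < cfg.min_events:
        raise ValueError(
            f"sample {events.sample_id!r}: only {mask.sum()} lower-slope events "
            f"in acceptor window [{lo:.0f}, {hi:.0f}] AFU, need >= {cfg.min_events}"
        )
    return robust_origin_slope(events.donor[mask], events.fret[mask])


def classify_sample(
    events: EventTable,
    wt_reference: EventTable,
    cfg: GatingConfig = GatingConfig(),
) -> tuple[ClassifiedEvents, float]:
    """Full per-sample gating: pre-gate, WT scatter, iterative fit, labels,
    windowed gradient.  Returns (classified events, reported gradient).

    The wild-type* residual SD is measured around the robust WT slope and
    reused for this sample, as wild-type* cells contain no aggregates.
    """
    wt_slope = robust_origin_slope(wt_reference.donor, wt_reference.fret)
    wt_sd = wt_residual_sd(wt_reference, wt_slope)
    pregated = pregate_high_fret(events, wt_reference)
    fit = iterative_slope_fit(events, cfg, wt_sd, retained=~pregated)
    classified = classify(events, fit, cfg, wt_sd, pregated=pregated)
    gradient = lower_slope_gradient(classified, events, cfg)
    return classified, gradient
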