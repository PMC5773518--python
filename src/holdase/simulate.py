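"""Synthetic flow-FRET event tables and denaturation curves with ground truth.

The generator emulates the statistical structure the analysis assumes:

* per-cell biosensor expression T is lognormal, truncated below at the
  instrument analysis floor (upstream gating removes untransfected cells)
  and above at full scale (off-scale events are gated out);
* acceptor = T + noise and donor = d*T + noise with independent additive
  Gaussian channel noise (channels are pre-compensated);
* each cell's fraction folded f comes from the three-state chaperone
  equilibrium at that cell's biosensor concentration B = T * afu_to_uM and
  the condition's latent chaperone level C;
* soluble cells emit fret = donor * (slope_U + f*(slope_F - slope_U)) + noise,
  aggregated cells fret = donor * slope_A + noise, with
  slope_U < slope_F < slope_A (unfolded low FRET, folded medium, aggregated
  high);
* aggregation is a per-cell Bernoulli draw whose probability follows a
  Boltzmann sigmoid of log10 expression with midpoint linear in dG_F plus a
  condition offset.

Every sample carries its per-cell truth so classifier and pipeline
accuracy can be scored directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import ndtr, ndtri

from . import thermo
from .denaturation import DenaturationCurve, eval_two_state
from .events import EventTable
from .quantify import MutantSpec

__all__ = [
    "SimulationTruth",
    "DEFAULT_PANEL",
    "WT_ID",
    "simulate_sample",
    "simulate_panel",
    "simulate_denaturation",
    "write_truth_manifest",
]

WT_ID = "wild-type*"

#: Study-like panel: a hyperstable wild-type* anchor plus 12 destabilised
#: mutants evenly spanning -6..+1 kJ/mol, where the biosensor is informative.
DEFAULT_PANEL: tuple[MutantSpec, ...] = (
    MutantSpec(WT_ID, -25.0, include_in_deltaC=False),
) + tuple(
    MutantSpec(f"mut{i + 1:02d}", float(dg), True)
    for i, dg in enumerate(np.round(np.linspace(-6.0, 1.0, 12), 3))
)


@dataclass(frozen=True)
class SimulationTruth:
    """Generator parameters; the defaults define the simulated study.

    Slopes are FRET AFU per donor AFU; expression is log10-normal in AFU;
    concentrations in µM.  ``agg_x50_slope``/``agg_x50_intercept`` place the
    aggregation midpoint at ``slope*dG_F + intercept (+ offset under
    treatment)`` in log10 AFU.
    """

    panel: tuple[MutantSpec, ...] = DEFAULT_PANEL
    C_control: float = 0.0
    C_treatment: float = 1.0
    K_d: float = 2.0
    afu_to_uM: float = 3e-4
    donor_per_expression: float = 1.0
    slope_U: float = 0.2
    slope_F: float = 0.6
    slope_A: float = 1.2
    noise_sd: float = 60.0
    expr_mean_log10: float = 3.5
    expr_sd_log10: float = 0.5
    expr_min_log10: float = 2.5
    expr_max_log10: float = 4.5
    agg_x50_slope: float = -0.07
    agg_x50_intercept: float = 3.6
    agg_x50_offset: float = 0.3
    agg_width: float = 0.2
    agg_min_prob: float = 0.02
    n_cells: int = 5000
    temperature: float = thermo.T_CELL
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.slope_U < self.slope_F < self.slope_A:
            raise ValueError(
                "slopes must order slope_U < slope_F < slope_A "
                f"(got {self.slope_U}, {self.slope_F}, {self.slope_A})"
            )
        for name in ("K_d", "afu_to_uM", "noise_sd", "agg_width", "donor_per_expression"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("C_control", "C_treatment"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    def mutant(self, mutant_id: str) -> MutantSpec:
        for m in self.panel:
            if m.mutant_id == mutant_id:
                return m
        raise KeyError(f"unknown mutant {mutant_id!r}")

    def chaperone(self, condition: str) -> float:
        if condition == "control":
            return self.C_control
        if condition == "treatment":
            return self.C_treatment
        raise ValueError(f"condition must be 'control' or 'treatment', got {condition!r}")

    def agg_x50(self, dG_F: float, condition: str) -> float:
        offset = self.agg_x50_offset if condition == "treatment" else 0.0
        return self.agg_x50_slope * dG_F + self.agg_x50_intercept + offset

    def aggregation_probability(self, log10_expression, dG_F: float, condition: str):
        """Per-cell aggregation probability: a Boltzmann sigmoid of log10
        expression with a nucleation floor.

        Aggregation is nucleated; below ``agg_min_prob`` the sigmoid tail is
        not populated within the expression time window, so hyperstable
        variants (wild-type*) never aggregate, as observed.
        """
        x50 = self.agg_x50(dG_F, condition)
        p = 1.0 / (1.0 + np.exp((x50 - np.asarray(log10_expression)) / self.agg_width))
        return np.where(p >= self.agg_min_prob, p, 0.0)


def _truncated_lognormal(rng, mean_log10, sd_log10, min_log10, max_log10, n):
    """Two-sided truncated log10-normal by inverse-CDF (upstream gating
    removes untransfected cells below and off-scale events above)."""
    a = ndtr((min_log10 - mean_log10) / sd_log10)
    b = ndtr((max_log10 - mean_log10) / sd_log10)
    u = rng.uniform(a, b, size=n)
    return 10.0 ** (mean_log10 + sd_log10 * ndtri(u))


def simulate_sample(
    truth: SimulationTruth,
    mutant_id: str,
    condition: str,
    n_cells: int | None = None,
    seed=None,
) -> EventTable:
    """Simulate one acquired sample (one mutant, condition, replicate).

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; identical
    seeds give bit-identical tables.
    """
    spec = truth.mutant(mutant_id)
    n = truth.n_cells if n_cells is None else n_cells
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    T = _truncated_lognormal(
        rng, truth.expr_mean_log10, truth.expr_sd_log10,
        truth.expr_min_log10, truth.expr_max_log10, n,
    )
    acceptor = np.maximum(T + rng.normal(0.0, truth.noise_sd, n), 1.0)
    donor = np.maximum(
        truth.donor_per_expression * T + rng.normal(0.0, truth.noise_sd, n), 1.0
    )

    K_f = thermo.kf_from_dg(thermo.FoldingParams(spec.dG_F, truth.temperature))
    B_cell = T * truth.afu_to_uM
    C = truth.chaperone(condition)
    if np.isinf(K_f):
        f = np.ones(n)
    else:
        f = thermo.fraction_folded_closed_form(K_f, truth.K_d, B_cell, C)

    p_agg = truth.aggregation_probability(np.log10(T), spec.dG_F, condition)
    aggregated = rng.uniform(size=n) < p_agg

    slope_soluble = truth.slope_U + f * (truth.slope_F - truth.slope_U)
    slope = np.where(aggregated, truth.slope_A, slope_soluble)
    fret = np.maximum(donor * slope + rng.normal(0.0, truth.noise_sd, n), 0.0)

    rep = 0
    return EventTable(
        sample_id=f"{mutant_id}|{condition}|r{rep}",
        mutant_id=mutant_id,
        condition=condition,
        replicate=rep,
        donor=donor,
        fret=fret,
        acceptor=acceptor,
        true_state=np.where(aggregated, "aggregated", "soluble"),
        true_fraction_folded=f,
    )


def simulate_panel(
    truth: SimulationTruth,
    replicates: int = 3,
    conditions: tuple[str, ...] = ("control", "treatment"),
    mutants: tuple[str, ...] | None = None,
    include_wt_reference: bool = True,
) -> list[EventTable]:
    """Simulate the full mutant x condition x replicate design.

    Sub-seeds are spawned deterministically from the master seed; each
    (condition, replicate) batch includes a wild-type* reference sample
    for gating unless the wild-type is already in ``mutants``.
    """
    if mutants is None:
        mutants = tuple(m.mutant_id for m in truth.panel)
    elif include_wt_reference and WT_ID not in mutants:
        mutants = (WT_ID,) + tuple(mutants)
    root = np.random.SeedSequence(truth.seed)
    children = iter(root.spawn(len(mutants) * len(conditions) * replicates))
    tables = []
    for mid in mutants:
        for cond in conditions:
            for rep in range(replicates):
                t = simulate_sample(truth, mid, cond, seed=next(children))
                t.sample_id = f"{mid}|{cond}|r{rep}"
                t.replicate = rep
                tables.append(t)
    return tables


def simulate_denaturation(
    panel: tuple[MutantSpec, ...] = DEFAULT_PANEL,
    m: float = 8.0,
    baselines: tuple[float, float, float, float] = (0.62, -0.004, 0.30, 0.003),
    urea: np.ndarray | None = None,
    noise_sd: float = 0.005,
    replicates: int = 3,
    temperature: float = thermo.T_ASSAY,
    seed: int = 0,
) -> tuple[list[DenaturationCurve], dict[str, float]]:
    """Urea series per mutant from the two-state model plus Gaussian noise.

    The midpoint is set from the folding free energy as D50 = -dG_F / m
    (the unfolding stability at 0 M urea is -dG_F), so destabilised mutants
    are partially unfolded already at 0 M.  Returns the curves and the true
    D50 per mutant.
    """
    if urea is None:
        urea = np.linspace(0.0, 6.0, 25)
    alpha_N, beta_N, alpha_D, beta_D = baselines
    rng = np.random.default_rng(seed)
    true_d50 = {s.mutant_id: -s.dG_F / m for s in panel}
    curves = []
    for rep in range(replicates):
        for s in panel:
            clean = eval_two_state(
                urea, m, true_d50[s.mutant_id], alpha_N, beta_N, alpha_D, beta_D,
                temperature,
            )
            curves.append(
                DenaturationCurve(
                    mutant_id=s.mutant_id,
                    urea=urea,
                    fret=clean + rng.normal(0.0, noise_sd, urea.size),
                    replicate=rep,
                )
            )
    return curves, true_d50


def write_truth_manifest(truth: SimulationTruth, path) -> None:
    """Dump the full generator parameterisation as JSON."""
    d = asdict(truth)
    d["panel"] = [asdict(m) for m in truth.panel]
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)
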