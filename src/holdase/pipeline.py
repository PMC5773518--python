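"""End-to-end analysis flows: events in, ΔC and ΔA50% reports out.

The pipeline mirrors how the assay is run: every acquisition batch
(condition x replicate) carries a wild-type* reference sample that sets
the gating scatter; each mutant sample is classified against its batch
reference; control-condition gradients calibrate the slope-to-fraction
map; and the panel statistics aggregate per-mutant values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import aggregation as agg
from . import quantify, simulate, thermo
from .classify import GatingConfig, classify_sample
from .denaturation import DenaturationCurve, fit_replicates, GlobalFitResult
from .events import EventTable, write_event_csv

logger = logging.getLogger("holdase")

__all__ = [
    "PipelineConfig",
    "run_holdase",
    "run_aggregation",
    "run_denaturation",
    "run_simulate",
    "read_denaturation_csv",
]

_GATING_KEYS = {
    "sd_multiplier",
    "n_iterations",
    "acceptor_range_fraction",
    "acceptor_bounds",
    "instrument_max_afu",
    "min_events",
}
_BINNING_KEYS = {"bounds", "n_bins", "min_cells", "low_aggregation_threshold"}
_TOP_KEYS = {
    "panel",
    "gating",
    "binning",
    "K_d_uM",
    "afu_to_uM",
    "temperature_K",
    "excluded_mutants",
    "B_estimator",
    "wt_id",
    "seed",
    "control_condition",
    "treatment_condition",
}


@dataclass
class PipelineConfig:
    """Validated run configuration; unknown keys are rejected on load."""

    panel: list[quantify.MutantSpec] = field(
        default_factory=lambda: list(simulate.DEFAULT_PANEL)
    )
    gating: GatingConfig = field(default_factory=GatingConfig)
    K_d_uM: float = 2.0
    afu_to_uM: float = 3e-4
    temperature_K: float = thermo.T_CELL
    bin_bounds: tuple[float, float] = agg.DEFAULT_LOG10_BOUNDS
    n_bins: int = 9
    min_cells_per_bin: int = 20
    low_aggregation_threshold: float = 20.0
    excluded_mutants: list[str] = field(default_factory=list)
    B_estimator: str = "slope_weighted"
    wt_id: str = simulate.WT_ID
    control_condition: str = "control"
    treatment_condition: str = "treatment"
    seed: int = 0

    @property
    def panel_dG(self) -> dict[str, float]:
        return {m.mutant_id: m.dG_F for m in self.panel}

    @property
    def included_mutants(self) -> list[str]:
        return [
            m.mutant_id
            for m in self.panel
            if m.include_in_deltaC and m.mutant_id not in self.excluded_mutants
        ]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        if "panel" in raw:
            kwargs["panel"] = [
                quantify.MutantSpec(
                    str(mid),
                    float(v["dG_F"] if isinstance(v, dict) else v),
                    bool(v.get("include_in_deltaC", True)) if isinstance(v, dict) else True,
                )
                for mid, v in raw["panel"].items()
            ]
        if "gating" in raw:
            unknown = set(raw["gating"]) - _GATING_KEYS
            if unknown:
                raise ValueError(f"unknown gating keys: {sorted(unknown)}")
            g = dict(raw["gating"])
            if g.get("acceptor_bounds") is not None:
                g["acceptor_bounds"] = tuple(g["acceptor_bounds"])
            kwargs["gating"] = GatingConfig(**g)
        if "binning" in raw:
            unknown = set(raw["binning"]) - _BINNING_KEYS
            if unknown:
                raise ValueError(f"unknown binning keys: {sorted(unknown)}")
            b = raw["binning"]
            if "bounds" in b:
                kwargs["bin_bounds"] = tuple(b["bounds"])
            if "n_bins" in b:
                kwargs["n_bins"] = int(b["n_bins"])
            if "min_cells" in b:
                kwargs["min_cells_per_bin"] = int(b["min_cells"])
            if "low_aggregation_threshold" in b:
                kwargs["low_aggregation_threshold"] = float(b["low_aggregation_threshold"])
        for key, attr in [
            ("K_d_uM", "K_d_uM"),
            ("afu_to_uM", "afu_to_uM"),
            ("temperature_K", "temperature_K"),
            ("excluded_mutants", "excluded_mutants"),
            ("B_estimator", "B_estimator"),
            ("wt_id", "wt_id"),
            ("seed", "seed"),
            ("control_condition", "control_condition"),
            ("treatment_condition", "treatment_condition"),
        ]:
            if key in raw:
                kwargs[attr] = raw[key]
        return cls(**kwargs)

    def config_hash(self) -> str:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _batches(tables: list[EventTable]) -> dict[tuple[str, int], list[EventTable]]:
    out: dict[tuple[str, int], list[EventTable]] = {}
    for t in tables:
        out.setdefault((t.condition, t.replicate), []).append(t)
    return out


def _wt_reference(batch: list[EventTable], wt_id: str, key) -> EventTable:
    wt = [t for t in batch if t.mutant_id == wt_id]
    if not wt:
        raise ValueError(
            f"batch {key}: no wild-type* reference sample ({wt_id!r}) present"
        )
    return wt[0]


def classify_all(
    tables: list[EventTable], config: PipelineConfig
) -> pd.DataFrame:
    """Classify every sample against its batch wild-type* reference.

    Returns a per-sample summary frame (gradient, percent_upper, counts)
    and attaches the classification to each table as ``_classified``.
    """
    rows = []
    for key, batch in sorted(_batches(tables).items()):
        wt = _wt_reference(batch, config.wt_id, key)
        for t in batch:
            classified, gradient = classify_sample(t, wt, config.gating)
            t._classified = classified  # cached for downstream steps
            t._gradient = gradient
            n = len(t)
            n_upper = int(np.isin(classified.labels, ("upper", "pregated_high")).sum())
            n_pregated = int((classified.labels == "pregated_high").sum())
            logger.info(
                "sample %s: n=%d upper=%d (pregated=%d) gradient=%.4f kept=%.3f",
                t.sample_id, n, n_upper, n_pregated, gradient,
                classified.slope_fit.kept_fraction,
            )
            rows.append(
                {
                    "sample_id": t.sample_id,
                    "mutant_id": t.mutant_id,
                    "condition": t.condition,
                    "replicate": t.replicate,
                    "n_events": n,
                    "n_upper": n_upper,
                    "n_pregated": n_pregated,
                    "percent_upper": classified.percent_upper,
                    "gradient": gradient,
                    "wt_residual_sd": classified.slope_fit.wt_residual_sd,
                }
            )
    return pd.DataFrame(rows)


def run_holdase(
    config: PipelineConfig,
    tables: list[EventTable],
    outdir=None,
) -> quantify.DeltaCResult:
    """Full ΔC flow: classify, calibrate on control gradients, invert to
    fractions, apply the three-state model per mutant, panel statistics."""
    summary = classify_all(tables, config)
    ctrl = summary[summary.condition == config.control_condition]
    treat = summary[summary.condition == config.treatment_condition]
    missing = []
    for mid in config.included_mutants:
        for name, sub in (("control", ctrl), ("treatment", treat)):
            if not (sub.mutant_id == mid).any():
                missing.append(f"{mid}/{name}")
    if missing:
        raise ValueError(f"missing samples: {missing}")

    ctrl_gradients = ctrl.groupby("mutant_id")["gradient"].mean().to_dict()
    cal = quantify.calibrate_slope_to_fraction(
        ctrl_gradients, config.panel, config.temperature_K
    )
    logger.info("calibration: a=%.4f b=%.4f rms=%.4g", cal.a, cal.b, cal.residual_rms)

    # per-condition scalar B over control-condition events in the window,
    # weighted consistently with the slope estimator
    ctrl_tables = [t for t in tables if t.condition == config.control_condition]
    if config.B_estimator == "slope_weighted":
        pairs = [
            quantify.estimate_B_slope_weighted(
                t, config.afu_to_uM, config.gating, t._classified
            )
            for t in ctrl_tables
        ]
        B = float(sum(b * w for b, w in pairs) / sum(w for _, w in pairs))
    elif config.B_estimator == "geometric":
        b_vals = [
            quantify.estimate_B(t, config.afu_to_uM, config.gating, t._classified)
            for t in ctrl_tables
        ]
        B = float(np.exp(np.mean(np.log(b_vals))))
    else:
        raise ValueError(f"unknown B_estimator {config.B_estimator!r}")
    logger.info("B = %.3g µM (%s, %d control samples)",
                B, config.B_estimator, len(ctrl_tables))

    specs = {m.mutant_id: m for m in config.panel}
    per_mutant: dict[str, list[float]] = {}
    point: dict[str, float] = {}
    for mid in config.included_mutants:
        g_c = ctrl[ctrl.mutant_id == mid].set_index("replicate")["gradient"]
        g_t = treat[treat.mutant_id == mid].set_index("replicate")["gradient"]
        # point estimate from replicate-mean gradients: averaging before the
        # nonlinear inversion avoids the one-sided truncation bias at the
        # intrinsic-fraction boundary for control samples
        point[mid] = quantify.delta_c_per_mutant(
            float(g_c.mean()), float(g_t.mean()), cal, specs[mid],
            config.K_d_uM, B, config.temperature_K,
        )
        for rep in sorted(set(g_c.index) & set(g_t.index)):
            dc = quantify.delta_c_per_mutant(
                float(g_c[rep]), float(g_t[rep]), cal, specs[mid],
                config.K_d_uM, B, config.temperature_K,
            )
            per_mutant.setdefault(mid, []).append(dc)

    result = quantify.panel_delta_c(
        per_mutant, config.included_mutants, config.K_d_uM, point_estimates=point
    )
    if outdir is not None:
        _write_holdase(outdir, config, summary, cal, B, result)
    return result


def run_aggregation(
    config: PipelineConfig,
    tables: list[EventTable],
    outdir=None,
) -> tuple[agg.A50Landscape, agg.SharedSlopeRegression]:
    """Full A50% flow: classify, bin, Boltzmann fits, exclusions, shared-slope
    regression of log10(A50) on dG_F with the translational offset."""
    classify_all(tables, config)
    landscape = agg.A50Landscape(excluded=list(config.excluded_mutants))
    bin_rows = []
    flagged: set[str] = set()
    for t in tables:
        if t.mutant_id == config.wt_id and config.wt_id not in config.panel_dG:
            continue
        bins = agg.bin_events(
            t._classified, t,
            bounds=config.bin_bounds,
            n_bins=config.n_bins,
            min_cells=config.min_cells_per_bin,
        )
        for mp, cnt, pct in zip(bins.midpoints, bins.counts, bins.percent_upper):
            bin_rows.append(
                {
                    "sample_id": t.sample_id, "mutant_id": t.mutant_id,
                    "condition": t.condition, "replicate": t.replicate,
                    "log10_midpoint": mp, "n_cells": int(cnt), "percent_upper": pct,
                }
            )
        try:
            fit = agg.fit_boltzmann(
                bins, low_aggregation_threshold=config.low_aggregation_threshold
            )
        except agg.LowAggregationError as exc:
            logger.info("sample %s excluded from A50: %s", t.sample_id, exc)
            flagged.add(t.mutant_id)
            continue
        landscape.add(t.mutant_id, t.condition, fit.x50)
    landscape.excluded = sorted(set(landscape.excluded) | flagged)
    if all(m in landscape.excluded for m in config.panel_dG):
        raise ValueError("all mutants excluded from the A50 analysis")

    regression = agg.shared_slope_regression(
        landscape, config.panel_dG,
        config.control_condition, config.treatment_condition,
    )
    if outdir is not None:
        _write_aggregation(outdir, config, pd.DataFrame(bin_rows), landscape, regression)
    return landscape, regression


def run_denaturation(
    config: PipelineConfig,
    curves: list[DenaturationCurve],
    outdir=None,
) -> tuple[dict[str, float], dict[str, float], list[GlobalFitResult]]:
    """Global two-state fits, one per replicate set, averaged per mutant.

    Note the returned dG_F follows the unfolding-stability convention of
    the denaturation model (m*D50, positive = stable); negate to get the
    folding free energies used by the panel definition.
    """
    mean_dg, sd_dg, fits = fit_replicates(curves, temperature=thermo.T_ASSAY)
    if outdir is not None:
        _ensure(outdir)
        rows = [
            {
                "mutant_id": mid,
                "dG_unfold_kJ_mol": mean_dg[mid],
                "dG_fold_kJ_mol": -mean_dg[mid],
                "sd_kJ_mol": sd_dg[mid],
                "D50_M_mean": float(np.mean([f.D50[mid] for f in fits if mid in f.D50])),
            }
            for mid in mean_dg
        ]
        pd.DataFrame(rows).to_csv(f"{outdir}/denaturation_dG.csv", index=False)
        shared = pd.DataFrame(
            [
                {
                    "replicate": i, "m": f.m, "alpha_N": f.alpha_N, "beta_N": f.beta_N,
                    "alpha_D": f.alpha_D, "beta_D": f.beta_D,
                    "residual_rms": f.residual_rms,
                }
                for i, f in enumerate(fits)
            ]
        )
        shared.to_csv(f"{outdir}/denaturation_shared_params.csv", index=False)
        _write_run_info(outdir, config, ["denaturation_dG.csv", "denaturation_shared_params.csv"])
    return mean_dg, sd_dg, fits


def run_simulate(
    config: PipelineConfig,
    truth: simulate.SimulationTruth | None = None,
    replicates: int = 3,
    outdir=None,
) -> list[EventTable]:
    """Generate the full synthetic design and optionally write it to disk."""
    if truth is None:
        truth = simulate.SimulationTruth(
            panel=tuple(config.panel), K_d=config.K_d_uM,
            afu_to_uM=config.afu_to_uM, temperature=config.temperature_K,
            seed=config.seed,
        )
    tables = simulate.simulate_panel(truth, replicates=replicates)
    if outdir is not None:
        _ensure(outdir)
        write_event_csv(tables, f"{outdir}/events.csv")
        truth_rows = []
        for t in tables:
            truth_rows.append(
                pd.DataFrame(
                    {
                        "sample_id": t.sample_id,
                        "true_state": t.true_state,
                        "true_fraction_folded": t.true_fraction_folded,
                    }
                )
            )
        pd.concat(truth_rows, ignore_index=True).to_csv(
            f"{outdir}/truth_per_cell.csv", index=False
        )
        simulate.write_truth_manifest(truth, f"{outdir}/truth_manifest.json")
        _write_run_info(outdir, config, ["events.csv", "truth_per_cell.csv", "truth_manifest.json"])
    return tables


def read_denaturation_csv(path) -> list[DenaturationCurve]:
    """Read curves from CSV with columns mutant_id, replicate, urea_M, fret_ratio."""
    df = pd.read_csv(path)
    needed = {"mutant_id", "replicate", "urea_M", "fret_ratio"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"denaturation CSV missing columns: {sorted(missing)}")
    curves = []
    for (mid, rep), g in df.groupby(["mutant_id", "replicate"]):
        g = g.sort_values("urea_M")
        curves.append(
            DenaturationCurve(
                mutant_id=str(mid),
                urea=g["urea_M"].to_numpy(),
                fret=g["fret_ratio"].to_numpy(),
                replicate=int(rep),
            )
        )
    return curves


def _ensure(outdir) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)


def _write_run_info(outdir, config: PipelineConfig, files: list[str]) -> None:
    info = {"config_hash": config.config_hash(), "files": files}
    with open(f"{outdir}/run_info.json", "w") as fh:
        json.dump(info, fh, indent=2)


def _write_holdase(outdir, config, summary, cal, B, result) -> None:
    _ensure(outdir)
    h = config.config_hash()
    summary.assign(config_hash=h).to_csv(f"{outdir}/classification_summary.csv", index=False)
    rows = [
        {
            "mutant_id": mid,
            "dG_F_kJ_mol": config.panel_dG[mid],
            "deltaC_uM": result.per_mutant[mid],
            "deltaC_over_Kd": result.per_mutant[mid] / config.K_d_uM,
            "n_replicates": len(result.per_mutant_replicates[mid]),
            "config_hash": h,
        }
        for mid in result.per_mutant
    ]
    pd.DataFrame(rows).to_csv(f"{outdir}/deltaC_per_mutant.csv", index=False)
    panel = {
        "deltaC_mean_uM": result.mean,
        "deltaC_sem_uM": result.sem,
        "deltaC_mean_over_Kd": result.mean_over_kd,
        "wilcoxon_p": result.p_value,
        "significance": _stars(result.p_value),
        "K_d_uM": config.K_d_uM,
        "B_uM": B,
        "calibration_a": cal.a,
        "calibration_b": cal.b,
        "config_hash": h,
    }
    with open(f"{outdir}/deltaC_panel.json", "w") as fh:
        json.dump(panel, fh, indent=2)
    _write_run_info(outdir, config, [
        "classification_summary.csv", "deltaC_per_mutant.csv", "deltaC_panel.json",
    ])


def _write_aggregation(outdir, config, bin_table, landscape, regression) -> None:
    _ensure(outdir)
    h = config.config_hash()
    bin_table.assign(config_hash=h).to_csv(f"{outdir}/expression_bins.csv", index=False)
    rows = [
        {
            "mutant_id": m, "condition": c,
            "log10_A50_mean": float(np.mean(v)),
            "log10_A50_sem": float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
            "A50_AFU": 10.0 ** float(np.mean(v)),
            "n_replicates": len(v),
            "config_hash": h,
        }
        for (m, c), v in sorted(landscape.x50.items())
    ]
    pd.DataFrame(rows).to_csv(f"{outdir}/a50_landscape.csv", index=False)
    reg = {
        "common_slope_log10_per_kJ_mol": regression.slope,
        "intercept_control": regression.intercept_control,
        "intercept_treatment": regression.intercept_treatment,
        "deltaA50_offset_log10": regression.deltaA50_offset,
        "deltaA50_fold_change": 10.0 ** regression.deltaA50_offset,
        "f_test_p_shared_vs_separate": regression.f_test_p,
        "wilcoxon_p": regression.wilcoxon_p,
        "significance": _stars(regression.wilcoxon_p),
        "excluded_mutants": landscape.excluded,
        "config_hash": h,
    }
    with open(f"{outdir}/a50_regression.json", "w") as fh:
        json.dump(reg, fh, indent=2)
    _write_run_info(outdir, config, [
        "expression_bins.csv", "a50_landscape.csv", "a50_regression.json",
    ])


def _stars(p: float) -> str:
    """Star coding for reports; raw p values are always written alongside."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
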