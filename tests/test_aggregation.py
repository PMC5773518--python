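"""Expression binning, Boltzmann A50% fits and the shared-slope offset."""

import numpy as np
import pytest

from holdase import simulate
from holdase.aggregation import (
    A50Landscape,
    ExpressionBins,
    LowAggregationError,
    bin_events,
    boltzmann,
    fit_boltzmann,
    shared_slope_regression,
)
from holdase.classify import ClassifiedEvents, SlopeFit, classify_sample
from holdase.events import EventTable


def make_classified(acceptor, upper_mask):
    acceptor = np.asarray(acceptor, float)
    donor = np.full(acceptor.size, 1000.0)
    ev = EventTable("s", "m", "control", 0, donor, 0.5 * donor, acceptor)
    labels = np.where(upper_mask, "upper", "lower")
    fit = SlopeFit(0.5, 50.0, 1.0, 4)
    return ClassifiedEvents(labels=labels, slope_fit=fit), ev


def bins_from_curve(x50, width=0.2, n_per_bin=500, rng=None):
    """ExpressionBins built directly from Boltzmann probabilities."""
    mid = np.linspace(2.5, 4.5, 9)
    p = boltzmann(mid, x50, width) / 100.0
    if rng is None:
        pct = 100.0 * p
    else:
        pct = 100.0 * rng.binomial(n_per_bin, p) / n_per_bin
    step = mid[1] - mid[0]
    edges = np.concatenate([mid - step / 2, [mid[-1] + step / 2]])
    counts = np.full(9, n_per_bin)
    return ExpressionBins(mid, edges, counts, pct, counts > 0, 0)


class TestBinning:
    def test_default_midpoints_match_quarter_decade_grid(self):
        cls, ev = make_classified(10 ** np.linspace(2.5, 4.5, 2000), np.zeros(2000, bool))
        bins = bin_events(cls, ev)
        assert np.allclose(bins.midpoints, np.linspace(2.5, 4.5, 9))
        assert np.allclose(np.diff(bins.midpoints), 0.25)

    def test_homogeneous_aggregation_rate_in_every_bin(self, rng):
        acc = 10 ** rng.uniform(2.5, 4.5, 30000)
        upper = rng.uniform(size=acc.size) < 0.30
        bins = bin_events(*make_classified(acc, upper))
        assert np.all(np.abs(bins.percent_upper - 30.0) < 4.0)

    def test_edge_value_assigned_to_higher_bin(self):
        # a cell exactly on the 10^(2.625) edge belongs to the 10^2.75 bin
        acc = np.concatenate([np.full(30, 10 ** 2.625), np.full(30, 10 ** 3.0)])
        bins = bin_events(*make_classified(acc, np.zeros(60, bool)), min_cells=1)
        assert bins.counts[1] == 30  # midpoint 2.75
        assert bins.counts[0] == 0

    def test_cell_accounting_conserved(self, rng):
        acc = 10 ** rng.uniform(2.0, 5.0, 5000)  # some cells out of bounds
        upper = rng.uniform(size=acc.size) < 0.2
        bins = bin_events(*make_classified(acc, upper))
        assert bins.counts.sum() + bins.n_out_of_bounds == acc.size

    def test_narrow_bounds_rejected(self):
        cls, ev = make_classified(np.full(100, 1000.0), np.zeros(100, bool))
        with pytest.raises(ValueError, match="decade"):
            bin_events(cls, ev, bounds=(3.0, 3.5))


class TestBoltzmannFit:
    def test_noiseless_recovery(self):
        fit = fit_boltzmann(bins_from_curve(3.5, 0.2))
        assert fit.x50 == pytest.approx(3.5, abs=1e-6)
        assert fit.width == pytest.approx(0.2, abs=1e-6)
        assert fit.A50 == pytest.approx(10 ** 3.5, rel=1e-4)

    def test_binomial_sampling_recovery_over_many_seeds(self):
        # 500 cells per bin: midpoint recovered within 0.05 log10 units
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fit = fit_boltzmann(bins_from_curve(3.5, 0.2, 500, rng))
            errs.append(fit.x50 - 3.5)
        assert np.max(np.abs(errs)) < 0.05

    def test_low_aggregator_flagged(self):
        bins = bins_from_curve(6.0, 0.2)  # never reaches 20%
        with pytest.raises(LowAggregationError):
            fit_boltzmann(bins)

    def test_insufficient_bins_rejected(self):
        b = bins_from_curve(3.5)
        b.usable = np.arange(9) < 3
        with pytest.raises(ValueError, match="usable"):
            fit_boltzmann(b)


def make_landscape(dg, slope, icpt_c, icpt_t, noise_sd, rng, reps=3):
    land = A50Landscape()
    for i, d in enumerate(dg):
        for _ in range(reps):
            land.add(f"m{i}", "control", slope * d + icpt_c + rng.normal(0, noise_sd))
            land.add(f"m{i}", "treatment", slope * d + icpt_t + rng.normal(0, noise_sd))
    return land, {f"m{i}": d for i, d in enumerate(dg)}


class TestSharedSlopeRegression:
    DG = np.linspace(-6.0, 1.0, 12)

    def test_exact_recovery_without_noise(self, rng):
        land, panel = make_landscape(self.DG, -0.07, 3.6, 3.9, 0.0, rng, reps=1)
        reg = shared_slope_regression(land, panel, "control", "treatment")
        assert reg.slope == pytest.approx(-0.07, abs=1e-10)
        assert reg.deltaA50_offset == pytest.approx(0.3, abs=1e-10)
        assert all(v == pytest.approx(0.3, abs=1e-10) for v in reg.per_mutant_delta.values())

    def test_offset_recovery_at_panel_noise(self, rng):
        land, panel = make_landscape(self.DG, -0.07, 3.6, 3.75, 0.05, rng)
        reg = shared_slope_regression(land, panel, "control", "treatment")
        assert reg.deltaA50_offset == pytest.approx(0.15, abs=0.06)
        assert reg.wilcoxon_p < 0.05

    def test_f_test_calibrated_under_shared_truth(self):
        # the extra-sum-of-squares test should rarely reject a true shared slope
        rejections = 0
        n_sim = 200
        for seed in range(n_sim):
            rng = np.random.default_rng(1000 + seed)
            land, panel = make_landscape(self.DG, -0.07, 3.6, 3.9, 0.05, rng)
            reg = shared_slope_regression(land, panel, "control", "treatment")
            rejections += reg.f_test_p < 0.05
        assert rejections / n_sim <= 0.10

    def test_f_test_power_against_doubled_slope(self):
        rejections = 0
        n_sim = 50
        for seed in range(n_sim):
            rng = np.random.default_rng(2000 + seed)
            land = A50Landscape()
            for i, d in enumerate(self.DG):
                for _ in range(3):
                    land.add(f"m{i}", "control", -0.07 * d + 3.6 + rng.normal(0, 0.05))
                    land.add(f"m{i}", "treatment", -0.14 * d + 3.6 + rng.normal(0, 0.05))
            panel = {f"m{i}": d for i, d in enumerate(self.DG)}
            reg = shared_slope_regression(land, panel, "control", "treatment")
            rejections += reg.f_test_p < 0.05
        assert rejections / n_sim > 0.9

    def test_identical_conditions_give_zero_offset(self, rng):
        land, panel = make_landscape(self.DG, -0.07, 3.6, 3.6, 0.0, rng, reps=1)
        reg = shared_slope_regression(land, panel, "control", "treatment")
        assert reg.deltaA50_offset == pytest.approx(0.0, abs=1e-12)

    def test_excluded_mutants_stay_out(self, rng):
        land, panel = make_landscape(self.DG, -0.07, 3.6, 3.9, 0.0, rng, reps=1)
        land.excluded = ["m0"]
        reg = shared_slope_regression(land, panel, "control", "treatment")
        assert "m0" not in reg.per_mutant_delta

    def test_too_few_mutants_rejected(self, rng):
        land, panel = make_landscape(self.DG[:3], -0.07, 3.6, 3.9, 0.0, rng, reps=1)
        with pytest.raises(ValueError):
            shared_slope_regression(land, panel, "control", "treatment")


class TestEventLevelLandscape:
    def test_fitted_a50_monotone_in_stability(self, panel_tables, default_truth, default_config):
        """More stable mutants aggregate at higher expression: fitted A50
        should rank-correlate with -dG_F across the panel."""
        from holdase.pipeline import run_aggregation
        from scipy.stats import spearmanr

        land, _ = run_aggregation(default_config, panel_tables)
        mutants = land.mutants(["control"])
        x50 = [land.mean_x50(m, "control") for m in mutants]
        dg = [default_config.panel_dG[m] for m in mutants]
        rho, _ = spearmanr(dg, x50)
        assert rho < -0.9  # lower (more stable) dG -> higher A50
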