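"""Lower/Upper-slope gating: pre-gate, robust fit, iterative exclusion."""

from dataclasses import replace

import numpy as np
import pytest

from holdase import simulate
from holdase.classify import (
    GatingConfig,
    classify,
    classify_sample,
    iterative_slope_fit,
    lower_slope_gradient,
    pregate_high_fret,
    robust_origin_slope,
    wt_residual_sd,
)
from holdase.events import EventTable
from holdase.quantify import MutantSpec


def make_table(donor, fret, acceptor=None, sid="s", **kw):
    donor = np.asarray(donor, float)
    if acceptor is None:
        acceptor = donor
    return EventTable(sid, kw.get("mutant_id", "m"), kw.get("condition", "control"),
                      0, donor, np.asarray(fret, float), np.asarray(acceptor, float))


@pytest.fixture(scope="module")
def wt_sample(default_truth):
    return simulate.simulate_sample(default_truth, simulate.WT_ID, "control", seed=101)


class TestPregate:
    def test_no_events_pregated_against_itself(self, wt_sample):
        assert pregate_high_fret(wt_sample, wt_sample).sum() == 0

    def test_single_constructed_outlier(self):
        donor = np.linspace(500, 5000, 300)
        wt = make_table(donor, 0.6 * donor)
        fret = 0.6 * donor.copy()
        fret[17] = 1.2 * donor[17]  # twice the maximal WT ratio
        ev = make_table(donor, fret)
        mask = pregate_high_fret(ev, wt)
        assert mask.sum() == 1 and mask[17]

    def test_empty_reference_rejected(self, wt_sample):
        with pytest.raises(ValueError):
            EventTable("e", "m", "c", 0, np.array([]), np.array([]), np.array([]))


class TestWtResidualSd:
    def test_zero_for_collinear_events(self):
        donor = np.linspace(100, 1000, 500)
        assert wt_residual_sd(make_table(donor, 0.5 * donor), 0.5) == 0.0

    def test_recovers_known_noise_sd(self, rng):
        donor = rng.uniform(500, 5000, 5000)
        fret = 0.6 * donor + rng.normal(0, 10.0, donor.size)
        est = wt_residual_sd(make_table(donor, fret), 0.6)
        assert est == pytest.approx(10.0, rel=0.03)

    def test_scale_equivariance(self, rng):
        donor = rng.uniform(500, 5000, 2000)
        resid = rng.normal(0, 25.0, donor.size)
        sd1 = wt_residual_sd(make_table(donor, 0.6 * donor + resid), 0.6)
        sd2 = wt_residual_sd(make_table(donor, 0.6 * donor + 2 * resid), 0.6)
        assert sd2 == pytest.approx(2 * sd1, rel=1e-9)


class TestIterativeSlopeFit:
    def test_pure_soluble_sample(self, default_truth):
        s = simulate.simulate_sample(default_truth, simulate.WT_ID, "control", seed=5)
        fit = iterative_slope_fit(s, GatingConfig(), wt_sd=70.0)
        assert fit.gradient == pytest.approx(0.6, rel=0.01)
        assert fit.kept_fraction > 0.95
        assert fit.iterations_run == 4

    def test_forty_percent_contamination_at_3x_slope(self, rng):
        n = 5000
        donor = 10 ** rng.uniform(2.5, 4.5, n)
        agg = rng.uniform(size=n) < 0.40
        slope = np.where(agg, 1.8, 0.6)
        fret = np.maximum(donor * slope + rng.normal(0, 60.0, n), 0.0)
        fit = iterative_slope_fit(make_table(donor, fret), GatingConfig(), wt_sd=80.0)
        assert fit.gradient == pytest.approx(0.6, rel=0.02)

    def test_collinear_events_exact_no_exclusions(self):
        donor = np.linspace(300, 3000, 1000)
        fit = iterative_slope_fit(make_table(donor, 0.45 * donor), GatingConfig(), wt_sd=50.0)
        assert fit.gradient == pytest.approx(0.45, rel=1e-12)
        assert fit.kept_fraction == 1.0

    def test_too_few_events_aborts(self):
        donor = np.linspace(300, 3000, 50)
        with pytest.raises(ValueError, match="events"):
            iterative_slope_fit(make_table(donor, 0.5 * donor), GatingConfig(), wt_sd=50.0)


class TestClassify:
    def test_wild_type_like_sample_sits_at_the_two_sd_floor(self, default_truth, wt_sample):
        # with zero aggregates, the only upper calls are the Gaussian
        # residual tail above the 2-SD band (~2.3% one-sided)
        other = simulate.simulate_sample(default_truth, simulate.WT_ID, "control", seed=55)
        classified, _ = classify_sample(other, wt_sample)
        assert classified.percent_upper < 4.0

    def test_agreement_with_generator_truth(self, default_truth, wt_sample):
        # well-separated aggregates at 30%: label agreement >= 98%
        t2 = replace(
            default_truth,
            panel=(MutantSpec("agg30", -25.0),),
            agg_x50_slope=0.0, agg_x50_intercept=3.7,
        )
        s = simulate.simulate_sample(t2, "agg30", "control", seed=77)
        load = (s.true_state == "aggregated").mean()
        assert 0.15 < load < 0.45
        classified, _ = classify_sample(s, wt_sample)
        pred = classified.labels != "lower"
        truth = s.true_state == "aggregated"
        assert (pred == truth).mean() >= 0.98

    def test_aggregates_pregated_or_upper(self, default_truth, wt_sample):
        # aggregated slope is 3x the WT slope here
        t2 = replace(
            default_truth,
            panel=(MutantSpec("agg", -25.0),),
            slope_A=1.8, agg_x50_slope=0.0, agg_x50_intercept=3.7,
        )
        s = simulate.simulate_sample(t2, "agg", "control", seed=78)
        classified, _ = classify_sample(s, wt_sample)
        agg_mask = s.true_state == "aggregated"
        caught = (classified.labels[agg_mask] != "lower").mean()
        assert caught >= 0.95

    def test_boundary_event_stays_lower(self):
        donor = np.linspace(300, 3000, 500)
        fret = 0.5 * donor
        fret[7] = 0.5 * donor[7] + 2.0 * 50.0  # exactly on the 2-SD boundary
        ev = make_table(donor, fret)
        fit = iterative_slope_fit(ev, GatingConfig(n_iterations=1), wt_sd=50.0)
        labels = classify(ev, fit, GatingConfig(), wt_sd=50.0).labels
        assert labels[7] == "lower"

    def test_label_partition_accounting(self, default_truth, wt_sample):
        s = simulate.simulate_sample(default_truth, "mut06", "control", seed=12)
        classified, _ = classify_sample(s, wt_sample)
        counts = {lab: int((classified.labels == lab).sum())
                  for lab in ("lower", "upper", "pregated_high")}
        assert sum(counts.values()) == len(s)


class TestLowerSlopeGradient:
    def test_windowed_matches_full_for_homogeneous_sample(self, default_truth, wt_sample):
        s = simulate.simulate_sample(default_truth, simulate.WT_ID, "control", seed=31)
        classified, windowed = classify_sample(s, wt_sample)
        assert windowed == pytest.approx(classified.slope_fit.gradient, rel=0.01)

    def test_window_excluding_everything_raises(self, default_truth, wt_sample):
        s = simulate.simulate_sample(default_truth, simulate.WT_ID, "control", seed=31)
        cfg = GatingConfig(acceptor_bounds=(1e7, 2e7))
        classified, _ = classify_sample(s, wt_sample)
        with pytest.raises(ValueError, match="window"):
            lower_slope_gradient(classified, s, cfg)

    def test_extreme_fractions_reproduce_endpoint_slopes(self, default_truth, wt_sample):
        # fully folded -> slope_F; fully unfolded (huge chaperone) -> slope_U
        folded = simulate.simulate_sample(default_truth, simulate.WT_ID, "control", seed=41)
        _, g_f = classify_sample(folded, wt_sample)
        assert g_f == pytest.approx(0.6, rel=0.01)
        t_unf = replace(default_truth, C_control=1e6, K_d=1e-3)
        unfolded = simulate.simulate_sample(t_unf, "mut12", "control", seed=42)
        _, g_u = classify_sample(unfolded, wt_sample)
        assert g_u == pytest.approx(0.2, rel=0.01)


class TestDeterminism:
    def test_identical_inputs_identical_outputs(self, default_truth, wt_sample):
        s = simulate.simulate_sample(default_truth, "mut04", "treatment", seed=13)
        c1, g1 = classify_sample(s, wt_sample)
        c2, g2 = classify_sample(s, wt_sample)
        assert g1 == g2
        assert np.array_equal(c1.labels, c2.labels)

    def test_robust_slope_ignores_one_sided_outliers_better_than_ols(self, rng):
        donor = rng.uniform(500, 5000, 4000)
        fret = 0.5 * donor + rng.normal(0, 40, donor.size)
        out = rng.uniform(size=donor.size) < 0.1
        fret[out] = 1.5 * donor[out]
        robust = robust_origin_slope(donor, fret)
        ols = np.dot(donor, fret) / np.dot(donor, donor)
        assert abs(robust - 0.5) < abs(ols - 0.5)
        assert robust == pytest.approx(0.5, rel=0.02)
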