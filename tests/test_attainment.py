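"""Tests of free-drug exposure windows, PTA and CFR."""

import numpy as np
import pytest

from dalbapk import (
    CFRResult,
    DoseEvent,
    MICDistribution,
    PKPDTargets,
    PopModel,
    Regimen,
    auc,
    cfr,
    default_mic_distribution,
    desirability,
    fauc_tail,
    load_regimen,
    pta,
    pta_curve,
    sample_population,
)
from dalbapk.attainment import EUCAST_MIC_GRID, evaluation_windows, resolve_target


def q3w():
    return load_regimen("1500-q3w")


class TestTargetsAndScenarios:
    def test_threshold_values_strictly_increasing(self):
        t = PKPDTargets()
        assert t.stasis == 27.1 and t.log1kill == 53.3 and t.log2kill == 111.1
        with pytest.raises(ValueError):
            PKPDTargets(stasis=60.0, log1kill=53.3, log2kill=111.1)

    def test_resolve_target(self):
        assert resolve_target("stasis") == 27.1
        assert resolve_target(40.0) == 40.0
        with pytest.raises(ValueError):
            resolve_target("bacteriostasis")


class TestEvaluationWindows:
    def test_simple_cycle_ends_at_last_redose(self):
        w = evaluation_windows(q3w())
        assert w == [(6 * 504.0 - 24.0, 6 * 504.0)]

    def test_two_dose_cycle_has_two_windows(self):
        r = load_regimen("1500-d1-d8-q6w")
        w = evaluation_windows(r)
        last_start = 5 * 1008.0
        assert (last_start + 168.0 - 24.0, last_start + 168.0) in w
        assert (6 * 1008.0 - 24.0, 6 * 1008.0) in w

    def test_no_cycle_length_errors(self, typical):
        r = Regimen((DoseEvent(0.0, 1500.0, 0.5),))
        with pytest.raises(ValueError, match="cycle_length"):
            fauc_tail(typical, r, 99.0)

    def test_interval_shorter_than_24h_errors(self, typical):
        r = Regimen((DoseEvent(0.0, 500.0, 0.5), DoseEvent(12.0, 500.0, 0.5)),
                    cycle_length=504.0, n_cycles=2)
        with pytest.raises(ValueError, match="24"):
            fauc_tail(typical, r, 99.0)


class TestFaucTail:
    def test_full_binding_gives_zero(self, typical):
        assert fauc_tail(typical, q3w(), 100.0) == 0.0

    def test_zero_binding_equals_total_auc(self, typical):
        t1 = 6 * 504.0
        assert fauc_tail(typical, q3w(), 0.0) == pytest.approx(
            auc(typical, q3w(), (t1 - 24.0, t1)), rel=1e-12
        )

    def test_pb99_vs_quadrature_oracle(self, typical):
        # oracle: trapezoid quadrature of the free-concentration curve
        from dalbapk import concentration

        t1 = 6 * 504.0
        grid = np.linspace(t1 - 24.0, t1, 200_001)
        free = 0.01 * concentration(typical, q3w(), grid)
        assert fauc_tail(typical, q3w(), 99.0) == pytest.approx(
            np.trapezoid(free, grid), rel=1e-4
        )

    def test_worst_window_is_cycle_end_for_d1_d8(self, typical):
        r = load_regimen("1500-d1-d8-q6w")
        windows = evaluation_windows(r)
        per_window = [auc(typical, r, w) for w in windows]
        assert fauc_tail(typical, r, 0.0) == pytest.approx(min(per_window), rel=1e-12)


class TestPTA:
    def test_zero_variability_is_step_function(self, popmodel, typical):
        m = PopModel(typical=typical, omega={"CL": 0.0, "V1": 0.0, "V2": 0.0},
                     error_b=0.0)
        pop = sample_population(m, 100, seed=0)
        mic_star = fauc_tail(typical, q3w(), 99.0) / 27.1
        assert pta(pop, q3w(), mic_star * 0.99, 99.0, 27.1) == 100.0
        assert pta(pop, q3w(), mic_star * 1.01, 99.0, 27.1) == 0.0

    def test_tiny_mic_attains_fully(self, pop10k):
        assert pta(pop10k, q3w(), 1e-9, 99.0, "stasis") == 100.0

    def test_invalid_inputs(self, pop10k):
        with pytest.raises(ValueError):
            pta(pop10k, q3w(), 0.0, 99.0, "stasis")

    def test_monotone_in_mic_pb_threshold_and_dose(self, popmodel):
        pop = sample_population(popmodel, 4000, seed=5)
        r = q3w()
        curve = pta_curve(pop, r, EUCAST_MIC_GRID, pb=99.0, threshold="stasis")
        assert np.all(np.diff(curve.pta) <= 1e-12)
        p93 = pta_curve(pop, r, EUCAST_MIC_GRID, pb=93.0, threshold="stasis")
        assert np.all(p93.pta >= curve.pta)
        stricter = pta_curve(pop, r, EUCAST_MIC_GRID, pb=99.0, threshold="log1kill")
        assert np.all(stricter.pta <= curve.pta)
        bigger = pta_curve(pop, r.scaled(1.5), EUCAST_MIC_GRID, pb=99.0, threshold="stasis")
        assert np.all(bigger.pta >= curve.pta)

    def test_single_mic_grid_equals_scalar(self, popmodel):
        pop = sample_population(popmodel, 1000, seed=6)
        curve = pta_curve(pop, q3w(), (0.125,), pb=99.0, threshold="stasis")
        assert curve.pta[0] == pta(pop, q3w(), 0.125, 99.0, "stasis")

    def test_unsorted_grid_errors(self, pop10k):
        with pytest.raises(ValueError, match="increasing"):
            pta_curve(pop10k, q3w(), (0.25, 0.125), pb=99.0)

    def test_monte_carlo_stability_10k_vs_100k(self, popmodel):
        # binomial error bound: PTA at n=10,000 within 1.5 points of n=100,000
        pop_small = sample_population(popmodel, 10_000, seed=1)
        pop_big = sample_population(popmodel, 100_000, seed=2)
        r = q3w()
        small = pta(pop_small, r, 0.125, 99.0, "stasis")
        big = pta(pop_big, r, 0.125, 99.0, "stasis")
        assert abs(small - big) < 1.5


class TestMICDistributionAndCFR:
    def test_packaged_snapshot_valid(self):
        dist = default_mic_distribution()
        assert sum(dist.frequencies) == pytest.approx(1.0, abs=1e-9)
        assert all(0.016 <= m <= 2.0 for m in dist.mics)

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="increasing"):
            MICDistribution((0.25, 0.125), (0.5, 0.5))
        with pytest.raises(ValueError, match="sum to 1"):
            MICDistribution((0.125, 0.25), (0.5, 0.4))
        with pytest.raises(ValueError, match="within"):
            MICDistribution((0.008, 0.125), (0.5, 0.5))

    def test_csv_round_trip(self, tmp_path):
        dist = default_mic_distribution()
        path = tmp_path / "mic.csv"
        dist.to_frame().to_csv(path, index=False)
        again = MICDistribution.from_csv(path)
        assert again.mics == dist.mics

    def test_point_mass_equals_pta(self, popmodel):
        pop = sample_population(popmodel, 2000, seed=8)
        curve = pta_curve(pop, q3w(), EUCAST_MIC_GRID, pb=99.0, threshold="stasis")
        point = MICDistribution((0.125,), (1.0,))
        assert cfr(curve, point).cfr == curve.value_at(0.125)

    def test_uniform_two_point_is_mean(self, popmodel):
        pop = sample_population(popmodel, 2000, seed=8)
        curve = pta_curve(pop, q3w(), EUCAST_MIC_GRID, pb=99.0, threshold="stasis")
        two = MICDistribution((0.06, 0.125), (0.5, 0.5))
        expected = 0.5 * (curve.value_at(0.06) + curve.value_at(0.125))
        assert cfr(curve, two).cfr == pytest.approx(expected, rel=1e-12)

    def test_cfr_bounded_by_pta_range(self, popmodel):
        pop = sample_population(popmodel, 2000, seed=8)
        curve = pta_curve(pop, q3w(), EUCAST_MIC_GRID, pb=99.0, threshold="stasis")
        result = cfr(curve, default_mic_distribution())
        assert curve.pta.min() <= result.cfr <= curve.pta.max()

    def test_mismatched_grid_lists_missing_mics(self, popmodel):
        pop = sample_population(popmodel, 500, seed=8)
        curve = pta_curve(pop, q3w(), (0.125, 0.25), pb=99.0, threshold="stasis")
        off_grid = MICDistribution((0.047, 0.125), (0.3, 0.7))
        with pytest.raises(ValueError, match="0.047"):
            cfr(curve, off_grid)

    def test_grid_refinement_outside_support_invariant(self, popmodel):
        pop = sample_population(popmodel, 2000, seed=8)
        dist = MICDistribution((0.06, 0.125), (0.4, 0.6))
        coarse = pta_curve(pop, q3w(), (0.06, 0.125), pb=99.0, threshold="stasis")
        fine = pta_curve(pop, q3w(), (0.016, 0.03, 0.06, 0.125, 0.5, 2.0),
                         pb=99.0, threshold="stasis")
        assert cfr(coarse, dist).cfr == pytest.approx(cfr(fine, dist).cfr, rel=1e-12)


class TestDesirability:
    def test_exact_bound_is_desirable(self):
        assert desirability(90.0) is True
        assert desirability(89.999) is False
        assert desirability(100.0) is True

    def test_cfr_object(self):
        r = CFRResult("x", 99.0, 27.1, cfr=91.2, n_subjects=10)
        assert desirability(r) is True
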