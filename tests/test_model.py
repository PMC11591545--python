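"""Unit and property tests of the analytic PK core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dalbapk import (
    DoseEvent,
    PKParams,
    Regimen,
    VAD_TYPICAL,
    auc,
    concentration,
    macro_constants,
    micro_rates,
    terminal_half_life,
)

from conftest import ode_concentration

param_strategy = st.builds(
    PKParams,
    CL=st.floats(0.01, 5.0),
    V1=st.floats(1.0, 50.0),
    Q=st.floats(0.01, 10.0),
    V2=st.floats(1.0, 100.0),
)


class TestMicroRates:
    def test_final_model_values(self, typical):
        k = micro_rates(typical)
        assert k.k10 == pytest.approx(0.050 / 6.5)
        assert k.k10 == pytest.approx(0.0076923, rel=1e-4)
        assert k.k12 == pytest.approx(0.073231, rel=1e-4)
        assert k.k21 == pytest.approx(0.030909, rel=1e-4)

    def test_identity_case(self):
        k = micro_rates(PKParams(CL=1, V1=1, Q=1, V2=1))
        assert (k.k10, k.k12, k.k21) == (1.0, 1.0, 1.0)

    def test_one_compartment_collapse(self):
        k = micro_rates(PKParams(CL=1, V1=1, Q=0.0, V2=1))
        assert k.k12 == 0.0 and k.k21 == 0.0

    @pytest.mark.parametrize("bad", [
        dict(CL=0, V1=6.5, Q=0.476, V2=15.4),
        dict(CL=0.05, V1=-1, Q=0.476, V2=15.4),
        dict(CL=0.05, V1=6.5, Q=-0.1, V2=15.4),
        dict(CL=0.05, V1=6.5, Q=0.476, V2=0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError, match="invalid parameter"):
            PKParams(**bad)


class TestMacroConstants:
    def test_final_model_roots_vs_eigenvalue_oracle(self, typical):
        # oracle: eigenvalues of the 2x2 rate matrix, computed numerically
        k = micro_rates(typical)
        K = np.array([[-(k.k10 + k.k12), k.k21], [k.k12, -k.k21]])
        lams = np.sort(-np.linalg.eigvals(K))
        mc = macro_constants(typical)
        assert mc.beta == pytest.approx(lams[0], rel=1e-10)
        assert mc.alpha == pytest.approx(lams[1], rel=1e-10)
        assert mc.beta == pytest.approx(2.17e-3, rel=1e-2)
        assert mc.alpha == pytest.approx(1.10e-1, rel=1e-2)

    def test_one_compartment_limit(self):
        mc = macro_constants(PKParams(CL=1, V1=1, Q=0.0, V2=1))
        assert mc.alpha == pytest.approx(1.0)
        assert mc.beta == 0.0
        assert mc.coefB == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(p=param_strategy)
    def test_vieta_identities(self, p):
        k = micro_rates(p)
        mc = macro_constants(p)
        assert mc.alpha >= mc.beta > 0
        assert mc.alpha * mc.beta == pytest.approx(k.k10 * k.k21, rel=1e-12)
        assert mc.alpha + mc.beta == pytest.approx(k.k10 + k.k12 + k.k21, rel=1e-12)


def single_dose(amount=1500.0, dur=0.5, start=0.0):
    return Regimen((DoseEvent(start, amount, dur),))


class TestConcentration:
    def test_no_events_is_zero(self, typical):
        r = Regimen(())
        assert concentration(typical, r, [100.0]) == pytest.approx(0.0)

    def test_empty_time_grid_errors(self, typical):
        with pytest.raises(ValueError, match="empty"):
            concentration(typical, single_dose(), [])

    def test_bolus_limit_is_dose_over_v1(self, typical):
        r = single_dose(dur=1e-6)
        c0 = concentration(typical, r, [1e-6])[0]
        assert c0 == pytest.approx(1500.0 / 6.5, rel=1e-4)

    def test_zero_before_first_dose_and_nonnegative(self, typical):
        r = single_dose(start=48.0)
        t = np.linspace(0.0, 1000.0, 200)
        c = concentration(typical, r, t)
        assert np.all(c[t <= 48.0] == 0.0)
        assert np.all(c >= 0.0)

    def test_matches_ode_oracle_final_model(self, typical):
        t = np.linspace(0.25, 1200.0, 200)
        ana = concentration(typical, single_dose(), t)
        ode = ode_concentration(typical, [(0.0, 1500.0, 0.5)], t)
        assert np.max(np.abs(ana - ode) / ode) < 1e-6

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_ode_oracle_random_params(self, seed):
        rng = np.random.default_rng(seed)
        p = PKParams(
            CL=float(rng.uniform(0.01, 2.0)),
            V1=float(rng.uniform(2.0, 30.0)),
            Q=float(rng.uniform(0.05, 5.0)),
            V2=float(rng.uniform(2.0, 60.0)),
        )
        doses = [(0.0, 1000.0, 1.0), (72.0, 500.0, 0.5)]
        r = Regimen(tuple(DoseEvent(s, a, d) for s, a, d in doses))
        t = np.linspace(0.5, 400.0, 200)
        ana = concentration(p, r, t)
        ode = ode_concentration(p, doses, t)
        assert np.max(np.abs(ana - ode) / np.maximum(ode, 1e-12)) < 1e-6

    def test_superposition_over_doses(self, typical):
        events = [DoseEvent(0.0, 1500.0, 0.5), DoseEvent(168.0, 1200.0, 0.5),
                  DoseEvent(504.0, 800.0, 1.0)]
        t = np.linspace(0.0, 1500.0, 97)
        combined = concentration(typical, Regimen(tuple(events)), t)
        summed = sum(concentration(typical, Regimen((e,)), t) for e in events)
        np.testing.assert_allclose(combined, summed, rtol=1e-10, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(p=param_strategy, c=st.floats(0.1, 10.0))
    def test_dose_linearity(self, p, c):
        r = Regimen((DoseEvent(0.0, 1000.0, 0.5), DoseEvent(24.0, 500.0, 2.0)))
        t = np.array([1.0, 10.0, 30.0, 100.0])
        base = concentration(p, r, t)
        scaled = concentration(p, r.scaled(c), t)
        np.testing.assert_allclose(scaled, c * base, rtol=1e-12)

    def test_cyclic_expansion_matches_explicit_events(self, typical):
        cyc = Regimen((DoseEvent(0.0, 1500.0, 0.5),), cycle_length=504.0, n_cycles=3)
        flat = Regimen(tuple(DoseEvent(504.0 * i, 1500.0, 0.5) for i in range(3)))
        t = np.linspace(0.0, 1600.0, 50)
        np.testing.assert_allclose(
            concentration(typical, cyc, t), concentration(typical, flat, t), rtol=1e-12
        )


class TestAUC:
    def test_no_events_zero(self, typical):
        assert auc(typical, Regimen(()), (0.0, 100.0)) == 0.0

    def test_bad_window_errors(self, typical):
        with pytest.raises(ValueError):
            auc(typical, single_dose(), (10.0, 10.0))
        with pytest.raises(ValueError):
            auc(typical, single_dose(), (10.0, 5.0))

    def test_auc_infinity_is_dose_over_clearance(self, typical):
        t_end = 20.0 * terminal_half_life(typical)
        total = auc(typical, single_dose(), (0.0, t_end))
        assert total == pytest.approx(1500.0 / 0.050, rel=1e-5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(p=param_strategy, split=st.floats(0.1, 0.9))
    def test_additivity_over_adjacent_windows(self, p, split):
        r = Regimen((DoseEvent(0.0, 1500.0, 0.5), DoseEvent(100.0, 700.0, 0.5)))
        a, b, c = 0.0, 300.0 * split, 300.0
        whole = auc(p, r, (a, c))
        parts = auc(p, r, (a, b)) + auc(p, r, (b, c))
        assert parts == pytest.approx(whole, rel=1e-9, abs=1e-12)

    def test_steady_state_tail_vs_quadrature_oracle(self, typical):
        # oracle: composite trapezoid on a 1-second grid over the window
        r = Regimen((DoseEvent(0.0, 1500.0, 0.5),), cycle_length=504.0, n_cycles=6)
        t0, t1 = 6 * 504.0 - 24.0, 6 * 504.0
        analytic = auc(typical, r, (t0, t1))
        grid = np.arange(t0, t1 + 1e-9, 1.0 / 3600.0)
        vals = concentration(typical, r, grid)
        quad = np.trapezoid(vals, grid)
        assert analytic == pytest.approx(quad, rel=1e-3)

    def test_dose_linearity(self, typical):
        r = single_dose()
        assert auc(typical, r.scaled(2.0), (0.0, 500.0)) == pytest.approx(
            2.0 * auc(typical, r, (0.0, 500.0)), rel=1e-12
        )


class TestHalfLife:
    def test_final_model_terminal_half_life(self, typical):
        # oracle: ln 2 / smallest-magnitude eigenvalue of the rate matrix
        k = micro_rates(typical)
        K = np.array([[-(k.k10 + k.k12), k.k21], [k.k12, -k.k21]])
        beta = float(np.min(-np.linalg.eigvals(K)))
        assert terminal_half_life(typical) == pytest.approx(np.log(2) / beta, rel=1e-10)
        assert terminal_half_life(typical) == pytest.approx(3.2e2, rel=0.01)

    def test_one_compartment_limit(self):
        assert terminal_half_life(PKParams(CL=1, V1=1, Q=0.0, V2=1)) == pytest.approx(
            np.log(2)
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(p=param_strategy, c=st.floats(0.1, 10.0))
    def test_time_scale_invariance(self, p, c):
        scaled = PKParams(CL=p.CL * c, V1=p.V1 * c, Q=p.Q * c, V2=p.V2 * c)
        assert terminal_half_life(scaled) == pytest.approx(
            terminal_half_life(p), rel=1e-9
        )


class TestRegimenValidation:
    def test_events_must_be_sorted(self):
        with pytest.raises(ValueError, match="sorted"):
            Regimen((DoseEvent(10.0, 100.0, 0.5), DoseEvent(0.0, 100.0, 0.5)))

    def test_expanded_times_strictly_increasing(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Regimen((DoseEvent(0.0, 100.0, 0.5), DoseEvent(600.0, 100.0, 0.5)),
                    cycle_length=504.0, n_cycles=2)

    def test_dose_event_validation(self):
        with pytest.raises(ValueError):
            DoseEvent(-1.0, 100.0, 0.5)
        with pytest.raises(ValueError):
            DoseEvent(0.0, 0.0, 0.5)
        with pytest.raises(ValueError):
            DoseEvent(0.0, 100.0, 0.0)

    def test_vss(self, typical):
        assert typical.vss == pytest.approx(21.9)
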