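"""Structural-model unit and property tests: right-hand sides, the window
switch, the algebraic drug concentration, and the integrators."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from vesselnorm import (
    ChemoParams,
    StructuralParams,
    chemo_concentration,
    normalization_factor,
    rhs_combo,
    rhs_treated,
    rhs_untreated,
    simulate_individual,
)
from vesselnorm._ode import predict_T

WINDOW = dict(t_norm1=53.4, t_norm2=59.2, N_max=6.7)
TYPICAL = dict(alpha_T=0.109, alpha_V=0.119, K=1.14, delta_V=0.115, T0=70.0)


def make_params(**over):
    kw = {**TYPICAL, **WINDOW}
    kw.update(over)
    return StructuralParams(**kw)


class TestNormalizationFactor:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (50.0, 1.0),      # before the window
            (55.0, 6.7),      # strictly inside
            (53.4, 1.0),      # boundary belongs to the outer branch
            (59.2, 1.0),
            (60.0, 1.0),
        ],
    )
    def test_branches(self, t, expected):
        assert normalization_factor(t, make_params()) == expected


class TestUntreatedRhs:
    def test_logistic_term_vanishes_at_capacity(self):
        p = make_params()
        dT, _ = rhs_untreated((123.0, 123.0), p)
        assert dT == pytest.approx(0.0, abs=1e-12)

    def test_half_capacity_growth(self):
        p = make_params(alpha_T=0.1)
        dT, _ = rhs_untreated((70.0, 140.0), p)
        assert dT == pytest.approx(0.1 * 70 * 0.5)  # = 3.5

    def test_capacity_growth_power_law(self):
        p = make_params(alpha_V=0.09)
        _, dV = rhs_untreated((70.0, 140.0), p)
        assert dV == pytest.approx(0.09 * 70 ** (2 / 3) * 140 ** (1 / 3))

    def test_rejects_nonpositive_state(self):
        with pytest.raises(ValueError):
            rhs_untreated((0.0, 100.0), make_params())


class TestTreatedRhs:
    def test_reduces_to_untreated(self):
        p = make_params(delta_V=0.0, N_max=1.0)
        for state in [(70.0, 80.0), (10.0, 400.0), (300.0, 120.0)]:
            for t in (40.0, 55.0, 65.0):
                assert rhs_treated(t, state, p) == pytest.approx(
                    rhs_untreated(state, p)
                )

    def test_growth_stops_at_effective_capacity(self):
        p = make_params()
        V = 50.0
        dT, _ = rhs_treated(55.0, (p.N_max * V, V), p)
        assert dT == pytest.approx(0.0, abs=1e-9)

    def test_pure_vessel_decay_at_vanishing_tumor(self):
        p = make_params(delta_V=0.1)
        _, dV = rhs_treated(40.0, (1e-9, 50.0), p)
        assert dV == pytest.approx(-0.1 * 50.0, rel=1e-3)


class TestChemoConcentration:
    def test_zero_outside_dosing_window(self):
        cp = ChemoParams(t_C_on=42, t_C_off=49)
        assert chemo_concentration(41.0, 80.0, 1.0, cp) == 0.0
        assert chemo_concentration(50.0, 80.0, 6.7, cp) == 0.0

    def test_peak_at_dose_time(self):
        cp = ChemoParams(alpha_C_tilde=1.0, t_C_on=42, t_C_off=49)
        # volumes enter the delivery term in ml: 80 mm^3 = 0.08 ml
        assert chemo_concentration(44.0, 80.0, 6.7, cp) == pytest.approx(
            1.0 * 6.7 * 0.08
        )

    def test_intra_day_decay(self):
        cp = ChemoParams(k=0.9, t_C_on=42, t_C_off=49)
        c0 = chemo_concentration(44.0, 80.0, 1.0, cp)
        c_half = chemo_concentration(44.5, 80.0, 1.0, cp)
        assert c_half == pytest.approx(c0 * np.exp(-0.45))

    def test_ordering_constraint(self):
        with pytest.raises(ValueError):
            ChemoParams(t_C_on=49, t_C_off=42)


class TestComboRhs:
    def test_no_kill_reduces_to_treated(self):
        p = make_params()
        cp = ChemoParams(delta_T=0.0, t_C_on=42, t_C_off=49)
        assert rhs_combo(44.0, (90.0, 85.0), p, cp) == pytest.approx(
            rhs_treated(44.0, (90.0, 85.0), p)
        )

    def test_outside_dosing_reduces_to_treated(self):
        p = make_params()
        cp = ChemoParams(t_C_on=42, t_C_off=49)
        assert rhs_combo(55.0, (90.0, 85.0), p, cp) == pytest.approx(
            rhs_treated(55.0, (90.0, 85.0), p)
        )

    def test_full_resistance_limit(self):
        p = make_params()
        cp = ChemoParams(lambda_=200.0, t_C_on=42, t_C_off=49)
        # days after onset, e^(-lambda*(t-on)) ~ 0: kill term vanishes
        assert rhs_combo(45.0, (90.0, 85.0), p, cp) == pytest.approx(
            rhs_treated(45.0, (90.0, 85.0), p), rel=1e-9
        )


class TestSimulateIndividual:
    def test_untreated_monotone_growth(self):
        p = StructuralParams(alpha_T=0.1, alpha_V=0.09, K=2.0, T0=70.0)
        tr = simulate_individual(p, np.linspace(38, 70, 33), model="untreated")
        assert np.all(np.diff(tr.T) > 0)

    def test_strong_vessel_kill_suppresses_growth(self):
        times = np.linspace(38, 70, 33)
        ctrl = simulate_individual(
            StructuralParams(alpha_T=0.1, alpha_V=0.09, K=2.0, T0=70.0),
            times, model="untreated")
        tr = simulate_individual(
            StructuralParams(alpha_T=0.1, alpha_V=0.09, K=2.0, T0=70.0,
                             delta_V=0.12, N_max=1.0),
            times, model="treated")
        assert np.all(np.diff(tr.V) < 0)
        assert tr.T[-1] < ctrl.T[-1]

    def test_reduction_oracle(self):
        """Treated model with delta_V=0, N_max=1 equals the untreated model."""
        times = np.linspace(38, 70, 17)
        p = make_params(delta_V=0.0, N_max=1.0)
        a = simulate_individual(p, times, model="untreated")
        b = simulate_individual(p, times, model="treated")
        np.testing.assert_allclose(a.T, b.T, rtol=1e-7)
        np.testing.assert_allclose(a.V, b.V, rtol=1e-7)

    def test_window_consistency_when_amplitude_is_one(self):
        times = np.linspace(38, 70, 17)
        a = simulate_individual(make_params(N_max=1.0), times, model="treated")
        b = simulate_individual(
            make_params(N_max=1.0, t_norm1=40.0, t_norm2=65.0), times,
            model="treated")
        np.testing.assert_allclose(a.T, b.T, rtol=1e-7)

    def test_grid_convergence(self):
        times = np.linspace(38, 70, 9)
        p = make_params()
        coarse = simulate_individual(p, times, model="treated", rtol=1e-8)
        fine = simulate_individual(p, times, model="treated", rtol=5e-9)
        assert abs(fine.T[-1] - coarse.T[-1]) / coarse.T[-1] < 1e-3

    def test_exponential_limit_inside_window(self):
        """With a huge window amplitude, in-window growth is exponential at
        rate alpha_T (the capacity constraint disappears)."""
        p = make_params(N_max=1e4, t_norm1=50.0, t_norm2=60.0, delta_V=0.05)
        times = np.linspace(51.0, 59.5, 35)
        p0 = make_params(N_max=1e4, t_norm1=50.0, t_norm2=60.0, delta_V=0.05)
        tr = simulate_individual(p0, np.concatenate([[38.0], times]),
                                 model="treated")
        logT = np.log(tr.T[1:])
        slope = np.polyfit(times, logT, 1)[0]
        assert slope == pytest.approx(p.alpha_T, rel=0.01)

    def test_positivity(self):
        """Trajectories stay positive over <= 100 days for a parameter grid."""
        times = np.linspace(38.0, 138.0, 51)
        for aT in (0.05, 0.3):
            for dv in (0.0, 0.3):
                for nm in (1.0, 50.0):
                    p = StructuralParams(alpha_T=aT, alpha_V=0.119, K=1.14,
                                         delta_V=dv, N_max=nm, t_norm1=53.4,
                                         t_norm2=59.2, T0=70.0)
                    tr = simulate_individual(p, times, model="treated")
                    assert tr.T.min() > 0 and tr.V.min() > 0

    @hsettings(max_examples=20, deadline=None)
    @given(
        aT=st.floats(0.02, 0.5),
        aV=st.floats(0.02, 0.5),
        K=st.floats(0.3, 5.0),
        dv=st.floats(0.0, 0.3),
        nm=st.floats(1.0, 100.0),
    )
    def test_positivity_property(self, aT, aV, K, dv, nm):
        p = StructuralParams(alpha_T=aT, alpha_V=aV, K=K, delta_V=dv,
                             N_max=nm, t_norm1=53.4, t_norm2=59.2, T0=70.0)
        tr = simulate_individual(p, np.linspace(38, 100, 32), model="treated",
                                 rtol=1e-6)
        assert tr.T.min() > 0 and tr.V.min() > 0

    def test_fast_integrator_matches_adaptive_solver(self):
        """The fixed-step path used inside estimation agrees with LSODA."""
        times = np.array([38.0, 42, 45, 49, 52, 56, 59, 63, 66, 70])
        p = make_params()
        ref = simulate_individual(p, times, model="treated")
        phi = np.array([p.alpha_T, p.alpha_V, p.K, p.delta_V, p.N_max,
                        p.t_norm1, p.t_norm2])
        fast = predict_T(times, p.T0, phi, True, 0.05)
        np.testing.assert_allclose(fast, ref.T, rtol=1e-6)

    def test_export_tidy_csv(self, tmp_path):
        p = make_params()
        tr = simulate_individual(p, np.linspace(38, 70, 9), model="treated")
        path = tmp_path / "traj.csv"
        tr.to_csv(path, id="m1")
        import pandas as pd
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["id", "time", "T", "V", "C", "N"]
        assert (frame["id"] == "m1").all()

    def test_input_validation(self):
        p = make_params()
        with pytest.raises(ValueError):
            simulate_individual(p, np.array([40.0, 39.0]), model="treated")
        with pytest.raises(ValueError):
            simulate_individual(p, np.linspace(38, 70, 5), model="nope")
        with pytest.raises(ValueError):
            simulate_individual(p, np.linspace(38, 70, 5), model="combo")


class TestParamValidation:
    def test_invariants(self):
        with pytest.raises(ValueError):
            StructuralParams(alpha_T=-0.1, alpha_V=0.1, K=1.0)
        with pytest.raises(ValueError):
            StructuralParams(alpha_T=0.1, alpha_V=0.1, K=1.0,
                             t_norm1=60.0, t_norm2=50.0)
        with pytest.raises(ValueError):
            StructuralParams(alpha_T=0.1, alpha_V=0.1, K=1.0, beta=0.5,
                             gamma=0.4)

    def test_v0_derived_from_ratio(self):
        p = StructuralParams(alpha_T=0.1, alpha_V=0.1, K=1.14, T0=70.0)
        assert p.V0 == pytest.approx(1.14 * 70.0)
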