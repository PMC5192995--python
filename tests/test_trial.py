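"""Synthetic-trial generator tests: study structure, noise model, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vesselnorm import (
    PopulationModel,
    TrialDesign,
    draw_individual_params,
    kpl4_population,
    simulate_trial,
)
from vesselnorm._ode import predict_T


class TestDrawIndividualParams:
    def test_degenerate_iiv_returns_typical_values(self, pop):
        zero = PopulationModel(
            theta=pop.theta, omega={k: 0.0 for k in pop.omega}, b=pop.b,
            group_map=pop.group_map)
        p = draw_individual_params(zero, "vanucizumab", 1)
        assert p.alpha_T == pytest.approx(pop.theta["alpha_T"])
        assert p.N_max == pytest.approx(pop.theta["N_max"])
        assert p.delta_V == pytest.approx(pop.theta["delta_V_vanucizumab"])

    def test_control_arm_has_no_treatment_effect(self, pop):
        p = draw_individual_params(pop, "control", 5)
        assert p.delta_V == 0.0 and p.N_max == 1.0

    def test_lognormal_median_matches_typical_value(self, pop):
        draws = [draw_individual_params(pop, "control", s).alpha_T
                 for s in range(4000)]
        assert np.median(draws) == pytest.approx(0.109, rel=0.03)

    def test_window_start_cv_matches_fixed_iiv(self, pop):
        # conditioning on ordered windows (t_norm1 < t_norm2) trims the
        # tails a little, so the CV sits just below the nominal omega = 0.1
        draws = np.array([draw_individual_params(pop, "bevacizumab", s).t_norm1
                          for s in range(3000)])
        cv = draws.std() / draws.mean()
        assert cv == pytest.approx(0.1, rel=0.15)

    def test_unknown_arm_rejected(self, pop):
        with pytest.raises(KeyError, match="unknown arm"):
            draw_individual_params(pop, "placebo", 1)


class TestSimulateTrial:
    def test_default_design_has_300_records(self, trial):
        data, truth = trial
        assert len(data.frame) == 300
        assert data.frame.ID.nunique() == 30
        assert data.frame.groupby("ID").TIME.count().eq(10).all()
        assert len(truth) == 30

    def test_mean_initial_volume_near_70(self, pop, design):
        means = []
        for seed in range(8):
            data, _ = simulate_trial(pop, design, seed)
            means.append(data.frame[data.frame.TIME == 38.0].DV.mean())
        assert np.mean(means) == pytest.approx(70.0, rel=0.05)

    def test_noise_free_trial_is_deterministic_typical_trajectory(self, pop, design):
        exact = PopulationModel(
            theta=pop.theta, omega={k: 0.0 for k in pop.omega}, b=1e-12,
            group_map=pop.group_map)
        exact_design = TrialDesign(T0_cv=0.0)
        d1, _ = simulate_trial(exact, exact_design, 1)
        d2, _ = simulate_trial(exact, exact_design, 99)
        # all animals in one arm identical, independent of the seed
        np.testing.assert_allclose(d1.frame.DV.values, d2.frame.DV.values,
                                   rtol=1e-9)
        van = d1.frame[d1.frame.ARM == "vanucizumab"]
        phi = np.array([0.109, 0.119, 1.14, 0.115, 6.7, 53.4, 59.2])
        times = np.array(sorted(van.TIME.unique()))
        f = predict_T(times, 70.0, phi, True, 0.05)
        np.testing.assert_allclose(
            van.groupby("TIME").DV.mean().values, f, rtol=1e-6)

    def test_seed_determinism(self, pop, design):
        d1, t1 = simulate_trial(pop, design, 123)
        d2, t2 = simulate_trial(pop, design, 123)
        pd.testing.assert_frame_equal(d1.frame, d2.frame)
        pd.testing.assert_frame_equal(t1, t2)

    def test_proportional_residuals_are_standard_normal(self):
        """Pooled (y - f) / (b f) over a large control trial ~ N(0, 1)."""
        pop = PopulationModel(
            theta={"alpha_T": 0.109, "alpha_V": 0.119, "K": 1.14},
            omega={"alpha_T": 0.422, "alpha_V": 0.177, "K": 0.711},
            b=0.185, group_map={"control": {}})
        design = TrialDesign(arms=(("control", 60),))
        data, truth = simulate_trial(pop, design, 7)
        times = np.array(design.measurement_days)
        resid = []
        for _, row in truth.iterrows():
            phi = np.array([row.alpha_T, row.alpha_V, row.K, 0, 1, 0, 0])
            f = predict_T(times, row.T0, phi, False, 0.05)
            y = data.records_of(row.ID).DV.values
            resid.append((y - f) / (pop.b * f))
        resid = np.concatenate(resid)
        assert stats.kstest(resid, "norm").pvalue > 0.01

    def test_positive_observations(self, trial):
        data, _ = trial
        assert (data.frame.DV > 0).all()


class TestDesignValidation:
    def test_first_measurement_must_match_treatment_start(self):
        with pytest.raises(ValueError):
            TrialDesign(measurement_days=(40.0, 45.0), dose_days=(38.0,))

    def test_duplicate_records_rejected(self):
        from vesselnorm import LongDataset
        frame = pd.DataFrame({"ID": ["a", "a"], "TIME": [38.0, 38.0],
                              "DV": [70.0, 71.0], "ARM": ["control"] * 2})
        with pytest.raises(ValueError, match="duplicate"):
            LongDataset(frame)
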