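"""Model-selection workflow tests: structural variants, error models, and
the explicit diagnostics-override selection rule."""

import numpy as np
import pandas as pd
import pytest

from vesselnorm import (
    ModelSpec,
    SaemSettings,
    compare_error_models,
    fit_monotonic,
    fit_transient,
    residual_pattern_flag,
    select_model,
    simulate_trial,
)
from vesselnorm.saem import _Problem
from vesselnorm.workflow import SHARING_VARIANTS, ComparisonReport


@pytest.fixture(scope="module")
def mono_fit(trial, quick_settings):
    data, _ = trial
    return fit_monotonic(data, quick_settings)


class TestSpecs:
    def test_monotonic_has_no_window_parameters(self, trial):
        data, _ = trial
        pr = _Problem(data, ModelSpec(structural="monotonic"))
        names = set(p.name for p in pr.params)
        assert "N_max" not in names and "t_norm1" not in names
        assert {"delta_V_bevacizumab", "delta_V_vanucizumab"} <= names

    def test_separate_all_has_more_parameters_than_final(self, trial):
        data, _ = trial
        n_final = len(_Problem(data, ModelSpec(sharing="final")).params)
        n_sep = len(_Problem(data, ModelSpec(sharing="separate-all")).params)
        assert n_sep > n_final

    def test_window_iiv_fixed_in_every_variant(self, trial):
        data, _ = trial
        for sharing in SHARING_VARIANTS:
            pr = _Problem(data, ModelSpec(sharing=sharing))
            for p in pr.params:
                if p.slot in (5, 6):
                    assert p.omega_fixed == 0.1

    def test_unknown_sharing_rejected(self, trial):
        data, _ = trial
        with pytest.raises(ValueError, match="sharing"):
            fit_transient(data, "everything-shared")


class TestMonotonicMisfit:
    def test_residual_pattern_on_window_data(self, mono_fit):
        """A monotonic fit to window-bearing data underestimates the
        in-window growth burst and overestimates the post-window decline in
        the treated arms: the arm-mean CWRES curve shows a positive
        excursion followed by a negative one."""
        pat = residual_pattern_flag(mono_fit)
        means = pat["day_means"]
        assert max(means[56.0], means[59.0]) > 0.3
        assert min(means[63.0], means[66.0], means[70.0]) < 0
        assert pat["flag"]

    def test_no_window_estimates_reported(self, mono_fit):
        assert "N_max" not in mono_fit.theta_hat
        assert "t_norm1" not in mono_fit.theta_hat

    def test_clean_residuals_when_model_matches(self, transient_fit):
        pat = residual_pattern_flag(transient_fit)
        assert not pat["flag"]


class TestSelectModel:
    def _table(self, rows):
        fits = [None] * len(rows)
        table = pd.DataFrame(rows)
        return ComparisonReport(labels=list(table.label), fits=fits,
                                table=table, deltas=pd.DataFrame())

    def test_lower_bic_wins_without_misfit(self):
        rep = self._table([
            dict(label="A", loglik=-100, bic=250.0, d=10, n_obs=300,
                 b_hat=0.2, misfit_flag=False, worst_arm_mean_cwres=0.2),
            dict(label="B", loglik=-95, bic=270.0, d=15, n_obs=300,
                 b_hat=0.2, misfit_flag=False, worst_arm_mean_cwres=0.2),
        ])
        assert select_model(rep)["selected"] == "A"

    def test_tie_prefers_fewer_parameters(self):
        rep = self._table([
            dict(label="big", loglik=-95, bic=250.5, d=15, n_obs=300,
                 b_hat=0.2, misfit_flag=False, worst_arm_mean_cwres=0.2),
            dict(label="small", loglik=-100, bic=251.0, d=10, n_obs=300,
                 b_hat=0.2, misfit_flag=False, worst_arm_mean_cwres=0.2),
        ])
        verdict = select_model(rep)
        assert verdict["selected"] == "small"
        assert any("tie" in c for c in verdict["criteria"])

    def test_diagnostics_override_beats_bic(self):
        """The BIC-preferred model is rejected when it alone shows the
        transient residual pattern — the published reasoning."""
        rep = self._table([
            dict(label="monotonic", loglik=-100, bic=240.0, d=10, n_obs=300,
                 b_hat=0.2, misfit_flag=True, worst_arm_mean_cwres=1.6),
            dict(label="transient", loglik=-90, bic=260.0, d=15, n_obs=300,
                 b_hat=0.18, misfit_flag=False, worst_arm_mean_cwres=0.3),
        ])
        verdict = select_model(rep)
        assert verdict["selected"] == "transient"
        assert any("override" in c for c in verdict["criteria"])

    def test_requires_two_candidates(self, transient_fit):
        with pytest.raises(ValueError):
            select_model([transient_fit])

    def test_full_selection_on_window_data(self, mono_fit, transient_fit):
        verdict = select_model([mono_fit, transient_fit],
                               labels=["monotonic", "transient"])
        assert verdict["selected"] == "transient"


class TestErrorModels:
    def test_proportional_data_prefer_proportional_model(self, pop):
        from vesselnorm.trial import TrialDesign
        design = TrialDesign()
        data, _ = simulate_trial(pop, design, 13)
        init = dict(pop.theta, T0=70.0)
        rep = compare_error_models(
            data,
            SaemSettings(seed=4, n_burnin=150, n_smooth=100, n_chains=1,
                         init_theta=init, init_b=0.2, compute_rse=True),
        )
        assert rep.verdict["selected"] == "proportional"
        assert rep.verdict["minus_2_delta_ll"] < 0

    def test_additive_data_prefer_constant_model(self, pop, design):
        additive = type(pop)(
            theta=pop.theta, omega=pop.omega, b=30.0,
            group_map=pop.group_map, error_model="constant")
        data, _ = simulate_trial(additive, design, 14)
        init = dict(pop.theta, T0=70.0)
        rep = compare_error_models(
            data,
            SaemSettings(seed=5, n_burnin=150, n_smooth=100, n_chains=1,
                         init_theta=init, init_b=0.2, compute_rse=True),
        )
        assert rep.verdict["selected"] == "constant"
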