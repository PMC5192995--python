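"""Estimation-engine tests: information criteria, M-step algebra, marginal
likelihood against quadrature, empirical Bayes estimates, standard errors,
and determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from vesselnorm import (
    ModelSpec,
    PopulationModel,
    SaemSettings,
    TrialDesign,
    compute_bic,
    loglik_importance,
    map_individual,
    population_fit,
    saem_fit,
    simulate_trial,
    standard_errors,
)
from vesselnorm.trial import LongDataset


class TestBic:
    def test_zero_loglik_single_obs(self):
        assert compute_bic(0.0, 1, 1) == 0.0

    def test_hand_computation(self):
        assert compute_bic(-1000.0, 300, 10) == pytest.approx(
            2000.0 + 10 * np.log(300))

    def test_penalty_grows_with_n(self):
        bics = [compute_bic(-100.0, n, 5) for n in (10, 100, 1000)]
        assert bics == sorted(bics)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_bic(0.0, 0, 1)


class TestMStepAlgebra:
    def test_conjugate_updates_maximize_complete_data_likelihood(self):
        """The closed-form mean/variance updates match a numeric optimizer
        of the complete-data Gaussian likelihood for the same statistics."""
        rng = np.random.default_rng(0)
        z = rng.normal(0.4, 0.7, size=50)
        s1, s2, n = z.sum(), (z**2).sum(), len(z)
        mu_hat = s1 / n
        w2_hat = s2 / n - mu_hat**2

        def negq_mu(m):
            return (s2 - 2 * m * s1 + n * m**2) / (2 * w2_hat)

        assert minimize_scalar(negq_mu).x == pytest.approx(mu_hat, abs=1e-6)

        def negq_w2(w2):
            return 0.5 * n * np.log(w2) + (s2 - 2 * mu_hat * s1 + n * mu_hat**2) / (2 * w2)

        res = minimize_scalar(negq_w2, bounds=(1e-3, 10), method="bounded")
        assert res.x == pytest.approx(w2_hat, rel=1e-4)


class TestRecoverySmallNoise:
    def test_low_noise_low_iiv_recovery(self):
        """With small IIV and small error, the population estimates land
        close to the generating values."""
        pop = PopulationModel(
            theta={"alpha_T": 0.109, "alpha_V": 0.119, "K": 1.5},
            omega={"alpha_T": 0.05, "alpha_V": 0.05, "K": 0.05},
            b=0.02, group_map={"control": {}})
        design = TrialDesign(arms=(("control", 12),))
        data, _ = simulate_trial(pop, design, 3)
        fit = saem_fit(
            data, ModelSpec(structural="untreated"),
            SaemSettings(seed=5, n_burnin=250, n_smooth=250, n_chains=1,
                         init_b=0.1, compute_loglik=False, compute_rse=False))
        # alpha_V and K trade off along a mild ridge even in control data,
        # so "close" here is ~12%
        assert fit.theta_hat["alpha_T"] == pytest.approx(0.109, rel=0.12)
        assert fit.theta_hat["K"] == pytest.approx(1.5, rel=0.12)
        assert fit.theta_hat["alpha_V"] == pytest.approx(0.119, rel=0.12)
        assert fit.b_hat < 0.05


@pytest.fixture(scope="module")
def one_animal():
    pop = PopulationModel(
        theta={"alpha_T": 0.109, "alpha_V": 0.119, "K": 1.5},
        omega={"alpha_T": 0.3, "alpha_V": 0.1, "K": 0.3},
        b=0.15, group_map={"control": {}})
    design = TrialDesign(arms=(("control", 1),), T0_cv=0.25)
    data, _ = simulate_trial(pop, design, 11)
    theta = dict(pop.theta, T0=68.0)
    omega = dict(pop.omega, T0=0.25)
    fit = population_fit(data, ModelSpec(structural="untreated"),
                         theta, omega, pop.b)
    return data, fit, theta, omega, pop.b


class TestMarginalLoglik:
    def test_matches_quadrature_oracle(self, one_animal):
        """Defensive importance sampling agrees with tensor Gauss-Hermite
        quadrature over the 4 random effects of a single control animal."""
        data, fit, theta, omega, b = one_animal
        ll_is, se = loglik_importance(data, fit, n_is_samples=4000, seed=1)

        pr = fit._problem
        nodes, weights = np.polynomial.hermite_e.hermegauss(21)
        idx = np.where(pr.active_matrix(fit._omega)[0])[0]
        w = pr.omega_matrix(fit._omega)[0, idx]
        mu_row = pr.mu_matrix(fit._mu)[0]
        grids = np.meshgrid(*([nodes] * len(idx)), indexing="ij")
        wgrids = np.meshgrid(*([weights] * len(idx)), indexing="ij")
        pts = np.stack([g.ravel() for g in grids], axis=1)
        wts = np.prod(np.stack([g.ravel() for g in wgrids], axis=1), axis=1)
        lls = np.empty(len(pts))
        for s, x in enumerate(pts):
            z = mu_row.copy()
            z[idx] += x * w
            lls[s] = pr.loglik_animal(0, z, b)
        m = lls.max()
        ll_gh = m + np.log(np.sum(wts * np.exp(lls - m)) / (2 * np.pi) ** (len(idx) / 2))
        assert ll_is == pytest.approx(ll_gh, abs=max(3 * se, 0.1))

    def test_monte_carlo_error_shrinks_with_samples(self, one_animal):
        data, fit, *_ = one_animal
        _, se_small = loglik_importance(data, fit, n_is_samples=250, seed=2)
        _, se_big = loglik_importance(data, fit, n_is_samples=4000, seed=2)
        assert se_big < se_small

    def test_degenerate_random_effects_reduce_to_plugin_density(self):
        pop = PopulationModel(
            theta={"alpha_T": 0.109, "alpha_V": 0.119, "K": 1.5},
            omega={"alpha_T": 0.0, "alpha_V": 0.0, "K": 0.0},
            b=0.15, group_map={"control": {}})
        design = TrialDesign(arms=(("control", 2),), T0_cv=0.0)
        data, _ = simulate_trial(pop, design, 4)
        theta = dict(pop.theta, T0=70.0)
        omega = {k: 0.0 for k in ("alpha_T", "alpha_V", "K", "T0")}
        fit = population_fit(data, ModelSpec(structural="untreated"),
                             theta, omega, pop.b)
        ll, _ = loglik_importance(data, fit, 10, seed=0)
        pr = fit._problem
        direct = sum(pr.loglik_animal(i, pr.mu_matrix(fit._mu)[i], pop.b)
                     for i in range(pr.n))
        assert ll == pytest.approx(direct, abs=1e-6)


class TestMapIndividual:
    def test_recovers_generating_parameters_from_dense_low_noise_data(self):
        pop = PopulationModel(
            theta={"alpha_T": 0.109, "alpha_V": 0.119, "K": 1.5},
            omega={"alpha_T": 0.4, "alpha_V": 0.15, "K": 0.5},
            b=0.01, group_map={"control": {}})
        design = TrialDesign(arms=(("control", 3),),
                             measurement_days=tuple(np.arange(38.0, 71.0)))
        data, truth = simulate_trial(pop, design, 21)
        row = truth.iloc[1]
        params, etas = map_individual(data.records_of(row.ID), pop)
        assert params.alpha_V == pytest.approx(row.alpha_V, rel=0.05)
        assert params.K == pytest.approx(row.K, rel=0.05)
        assert params.T0 == pytest.approx(row.T0, rel=0.05)

    def test_single_noisy_observation_shrinks_to_prior_mode(self, pop):
        records = pd.DataFrame({"TIME": [38.0], "DV": [80.0],
                                "ARM": ["control"]})
        wide = PopulationModel(theta=pop.theta,
                               omega={k: v for k, v in pop.omega.items()},
                               b=1.0, group_map=pop.group_map)
        params, etas = map_individual(records, wide)
        for name, val in etas.items():
            if name != "T0":
                assert abs(val) < 0.15, name

    def test_requires_observations(self, pop):
        with pytest.raises(ValueError):
            map_individual(pd.DataFrame(columns=["TIME", "DV", "ARM"]), pop)


class TestStandardErrors:
    def test_duplicating_the_dataset_shrinks_rse_by_sqrt2(self, pop, design):
        data, _ = simulate_trial(pop, design, 8)
        theta = dict(pop.theta, T0=67.0)
        omega = dict(pop.omega, T0=0.29)
        fit1 = population_fit(data, ModelSpec(), theta, omega, pop.b)
        doubled = data.frame.copy()
        doubled["ID"] = doubled["ID"] + "-copy"
        big = LongDataset(pd.concat([data.frame, doubled], ignore_index=True))
        fit2 = population_fit(big, ModelSpec(), theta, omega, pop.b)
        r1 = standard_errors(fit1)
        r2 = standard_errors(fit2)
        ratios = [r1[k] / r2[k] for k in ("K", "t_norm1", "b")]
        for ratio in ratios:
            assert ratio == pytest.approx(np.sqrt(2), rel=0.15)

    def test_weakly_identified_amplitude_has_larger_rse_than_growth_rate(
            self, transient_fit):
        assert transient_fit.rse["N_max"] > transient_fit.rse["alpha_T"]

    def test_fixed_parameters_absent_from_rse(self, transient_fit):
        assert "omega_t_norm1" not in transient_fit.rse
        assert "omega_t_norm2" not in transient_fit.rse


class TestFitResult:
    def test_bic_identity(self, transient_fit):
        f = transient_fit
        assert f.bic == pytest.approx(compute_bic(f.loglik, f.n_obs, f.d))

    def test_parameter_count(self, transient_fit):
        # 9 typical values + 7 estimated IIVs (window IIVs fixed) + error
        assert transient_fit.d == 17

    def test_shrinkage_matches_hand_formula(self, transient_fit):
        f = transient_fit
        pr = f._problem
        for j, p in enumerate(pr.params):
            if p.name in f.shrinkage:
                eta = f._eta_hat[p.animal_idx, p.slot]
                hand = 1.0 - np.var(eta, ddof=1) / f._omega[j] ** 2
                assert f.shrinkage[p.name] == pytest.approx(hand)

    def test_ebe_and_population_views(self, transient_fit, trial):
        data, _ = trial
        assert set(transient_fit.ebe) == set(data.animals)
        popview = transient_fit.population()
        assert popview.theta["t_norm2"] > popview.theta["t_norm1"]
        assert popview.group_map["control"] == {}


class TestDeterminism:
    def test_same_seed_same_fit(self, trial, literature_init):
        data, _ = trial
        kw = dict(seed=11, n_burnin=40, n_smooth=30, n_chains=1,
                  init_theta=literature_init, init_b=0.2,
                  compute_loglik=False, compute_rse=False)
        f1 = saem_fit(data, ModelSpec(), SaemSettings(**kw))
        f2 = saem_fit(data, ModelSpec(), SaemSettings(**kw))
        for k in f1.theta_hat:
            assert f1.theta_hat[k] == f2.theta_hat[k]
        assert f1.b_hat == f2.b_hat
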