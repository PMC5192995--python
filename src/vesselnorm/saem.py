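"""Population-parameter estimation by stochastic-approximation EM (SAEM).

The mixed-effects model estimated here is

    y_ij = f(t_ij, phi_i) + g(t_ij, phi_i) * eps_ij,   eps_ij ~ N(0, 1),
    phi_i = theta * exp(eta_i),                        eta_i ~ N(0, diag(omega^2)),

with ``f`` the structural vascular tumor growth model and ``g = b*f``
(proportional) or ``g = b`` (constant).  Each SAEM iteration alternates a
Markov-chain Monte Carlo draw of the individual log-parameters (E-step), a
stochastic-approximation update of the complete-data sufficient statistics,
and a closed-form M-step (the log-normal/normal conjugacy makes the updates
exact means and variances).  Burn-in iterations use step size 1 with a
simulated-annealing floor on the variance parameters so the individual
samples can explore before the statistics are frozen in; smoothing
iterations use a 1/k Robbins-Monro schedule.

Internal parametrization.  Three individual parameters are estimated on
transformed scales that build the model's constraints into their supports:
the initial tumor volume T0 is a latent log-normal individual parameter
(the first record is then an ordinary noisy observation of it —
conditioning the initial state on the observed first value would make the
fitted model inconsistent with the assumed data-generating process and
measurably biases the growth-rate and error estimates); the window
amplitude is estimated as N_max - 1 >= 0 (the window can only enhance the
carrying capacity); and the window end is estimated through the window
LENGTH t_norm2 - t_norm1 > 0.  Estimating ordered window times as
independent log-normals truncated to t_norm1 < t_norm2 looks natural but is
statistically treacherous: the truncation removes a large fraction of the
prior mass, the naive M-step then drifts the window systematically wider,
and the truncation-corrected M-step is flat in the gap direction.  Reported
estimates (``theta_hat``, traces, tables) are always on the natural scale.

After convergence the marginal log-likelihood is recomputed by importance
sampling around each animal's empirical Bayes estimate (EBE), standard
errors come from a first-order linearization of the marginal model, and
shrinkage compares the EBE spread to the estimated population variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import minimize

from ._mcmc import animal_loglik, batch_loglik, mcmc_sweep, residual_sumsq
from ._ode import predict_T
from .models import StructuralParams
from .trial import SLOTS, LongDataset, PopulationModel

__all__ = [
    "ModelSpec",
    "SaemSettings",
    "FitResult",
    "saem_fit",
    "compute_bic",
    "loglik_importance",
    "map_individual",
    "standard_errors",
]

_TREAT_SLOTS = ("delta_V", "N_max", "t_norm1", "t_norm2")


@dataclass
class ModelSpec:
    """What to estimate: structural variant, error model, sharing rules.

    ``structural`` is one of ``untreated`` (no treatment parameters),
    ``monotonic`` (vessel kill only; N_max pinned at 1) or ``transient``
    (vessel kill + normalization window).  ``sharing`` controls how treatment
    parameters are pooled across treated arms: ``final`` gives each arm its
    own delta_V but shared window parameters, ``shared-delta`` pools
    everything, ``separate-all`` splits everything per arm.  IIV standard
    deviations named in ``fixed_omegas`` are held at the given value (the
    window times default to 0.1, expressing that the window is a property of
    the cell line/treatment rather than the individual).
    """

    structural: str = "transient"
    error_model: str = "proportional"
    sharing: str = "final"
    fixed: Dict[str, float] = field(default_factory=dict)
    fixed_omegas: Dict[str, float] = field(
        default_factory=lambda: {"t_norm1": 0.1, "t_norm2": 0.1}
    )
    control_arms: Tuple[str, ...] = ("control",)

    def __post_init__(self) -> None:
        if self.structural not in ("untreated", "monotonic", "transient"):
            raise ValueError(f"unknown structural model {self.structural!r}")
        if self.error_model not in ("proportional", "constant"):
            raise ValueError(f"unknown error model {self.error_model!r}")
        if self.sharing not in ("final", "shared-delta", "separate-all"):
            raise ValueError(f"unknown sharing variant {self.sharing!r}")


@dataclass
class SaemSettings:
    """Algorithm settings (Monolix-like defaults, all overridable)."""

    n_burnin: int = 500
    n_smooth: int = 500
    n_chains: int = 2
    n_mcmc_passes: int = 3
    n_freeze: int = 100
    seed: int = 1
    dt_max: float = 0.5
    anneal: float = 0.95
    omega_grow: float = 1.05
    omega_max: float = 2.0
    b_grow: float = 1.3
    step_init: float = 0.4
    init_theta: Dict[str, float] = field(default_factory=dict)
    init_omega: float = 0.3
    init_b: float = 0.3
    n_is_samples: int = 1000
    polish: bool = False
    polish_draws: int = 400
    polish_rounds: int = 3
    polish_maxiter: int = 15
    compute_loglik: bool = True
    compute_rse: bool = True


@dataclass
class _PopParam:
    name: str
    slot: int
    animal_idx: np.ndarray
    theta_fixed: Optional[float] = None
    omega_fixed: Optional[float] = None

    @property
    def estimated(self) -> bool:
        return self.theta_fixed is None

    @property
    def omega_estimated(self) -> bool:
        return self.estimated and self.omega_fixed is None


class _Problem:
    """Dataset + spec compiled into flat arrays for the numba kernels."""

    def __init__(self, data: LongDataset, spec: ModelSpec):
        self.data = data
        self.spec = spec
        frame = data.frame.sort_values(["ID", "TIME"], kind="stable")
        self.animals = list(dict.fromkeys(frame["ID"]))
        self.n = len(self.animals)
        self.arm_of = {a: data.arm_of(a) for a in self.animals}
        arms_in_order = list(dict.fromkeys(frame["ARM"]))
        self.treated_arms = [a for a in arms_in_order if a not in spec.control_arms]

        ys, ts = [], []
        for a in self.animals:
            sub = frame[frame["ID"] == a]
            ys.append(sub["DV"].to_numpy(dtype=float))
            ts.append(sub["TIME"].to_numpy(dtype=float))
        self.offsets = np.concatenate(([0], np.cumsum([len(y) for y in ys]))).astype(np.int64)
        self.y_flat = np.concatenate(ys)
        self.t_flat = np.concatenate(ts)
        self.T0s = np.array([y[0] for y in ys])
        # an "untreated" structural fit runs every animal without treatment
        # terms regardless of arm labels; the monotonic model is treated but
        # has no window
        self.windowed = spec.structural == "transient"
        self.treated = np.array(
            [
                spec.structural != "untreated"
                and self.arm_of[a] not in spec.control_arms
                for a in self.animals
            ]
        )
        self.n_obs = len(self.y_flat)

        # --- population parameters -------------------------------------
        slot_idx = {s: i for i, s in enumerate(SLOTS)}
        all_idx = np.arange(self.n)
        params: List[_PopParam] = []
        for s in ("alpha_T", "alpha_V", "K", "T0"):
            params.append(_PopParam(s, slot_idx[s], all_idx))
        arm_animals = {
            arm: np.array([i for i, a in enumerate(self.animals) if self.arm_of[a] == arm])
            for arm in self.treated_arms
        }
        treated_idx = np.array([i for i in all_idx if self.treated[i]])
        if spec.structural in ("monotonic", "transient") and self.treated_arms:
            if spec.sharing == "shared-delta":
                params.append(_PopParam("delta_V", slot_idx["delta_V"], treated_idx))
            else:
                for arm in self.treated_arms:
                    params.append(
                        _PopParam(f"delta_V_{arm}", slot_idx["delta_V"], arm_animals[arm])
                    )
        if spec.structural == "transient" and self.treated_arms:
            window = ("N_max", "t_norm1", "t_norm2")
            if spec.sharing == "separate-all":
                for arm in self.treated_arms:
                    for s in window:
                        params.append(
                            _PopParam(f"{s}_{arm}", slot_idx[s], arm_animals[arm])
                        )
            else:
                for s in window:
                    params.append(_PopParam(s, slot_idx[s], treated_idx))
        for p in params:
            base = SLOTS[p.slot]
            if p.name in spec.fixed:
                p.theta_fixed = float(spec.fixed[p.name])
            elif base in spec.fixed and base != p.name:
                p.theta_fixed = float(spec.fixed[base])
            if p.name in spec.fixed_omegas:
                p.omega_fixed = float(spec.fixed_omegas[p.name])
            elif base in spec.fixed_omegas and base != p.name:
                p.omega_fixed = float(spec.fixed_omegas[base])
        self.params = params
        self.param_names = [p.name for p in params]

        # per-animal slot -> param index map (-1 = inactive)
        self.slot_map = -np.ones((self.n, 8), dtype=np.int64)
        for k, p in enumerate(params):
            for i in p.animal_idx:
                self.slot_map[i, p.slot] = k

        # window pairs (t_norm1*, t_norm2*): slot 6 stores the log window
        # LENGTH, and the reported t_norm2 is t_norm1 + length
        name_to_idx = {p.name: j for j, p in enumerate(params)}
        self.window_pairs: List[Tuple[int, int]] = []
        for j, p in enumerate(params):
            if SLOTS[p.slot] == "t_norm1":
                other = "t_norm2" + p.name[len("t_norm1"):]
                if other in name_to_idx:
                    self.window_pairs.append((j, name_to_idx[other]))

        # physiological box for the individual parameters (truncated priors):
        # rates below 5/day and above ~0, capacity ratio within [1e-3, 100],
        # window amplitude above baseline within [1e-3, 1e4], window start
        # inside the observation horizon, window length within [0.25, 35]
        # days, initial volume within [1, 1e4] mm^3
        t_lo, t_hi = float(self.t_flat.min()), float(self.t_flat.max())
        self.lo = np.array([1e-4, 1e-4, 1e-3, 1e-6, 1e-3, t_lo, 0.25, 1.0])
        self.hi = np.array([5.0, 5.0, 100.0, 5.0, 1e4, t_hi, 35.0, 1e4])

    # -- vector <-> matrix plumbing -------------------------------------
    def mu_matrix(self, mu: np.ndarray) -> np.ndarray:
        out = np.zeros((self.n, 8))
        mask = self.slot_map >= 0
        out[mask] = mu[self.slot_map[mask]]
        return out

    def omega_matrix(self, omega: np.ndarray) -> np.ndarray:
        out = np.zeros((self.n, 8))
        mask = self.slot_map >= 0
        out[mask] = omega[self.slot_map[mask]]
        return out

    def active_matrix(self, omega: np.ndarray) -> np.ndarray:
        return (self.slot_map >= 0) & (self.omega_matrix(omega) > 0)

    def phi_of(self, z_row: np.ndarray, treated: bool) -> np.ndarray:
        """Natural-scale structural parameters from a log-parameter row."""
        phi = np.exp(z_row)
        if treated:
            phi = phi.copy()
            if self.windowed:
                phi[4] = 1.0 + phi[4]
                phi[6] = phi[5] + phi[6]
            else:
                phi[4] = 1.0
                phi[5] = 0.0
                phi[6] = 0.0
        return phi

    def report_theta(self, mu: np.ndarray) -> Dict[str, float]:
        """Population estimates on the reporting scale (N_max, t_norm2)."""
        out: Dict[str, float] = {}
        for j, p in enumerate(self.params):
            base = SLOTS[p.slot]
            if base == "N_max":
                out[p.name] = float(1.0 + np.exp(mu[j]))
            else:
                out[p.name] = float(np.exp(mu[j]))
        for j1, j2 in self.window_pairs:
            out[self.params[j2].name] = float(np.exp(mu[j1]) + np.exp(mu[j2]))
        return out

    def predict_animal(self, i: int, z_row: np.ndarray, dt_max: float = 0.05) -> np.ndarray:
        times = self.t_flat[self.offsets[i]:self.offsets[i + 1]]
        phi = self.phi_of(z_row, bool(self.treated[i]))
        return predict_T(times, phi[7], phi, bool(self.treated[i]), dt_max)

    def loglik_animal(self, i: int, z_row: np.ndarray, b: float, dt_max: float = 0.05) -> float:
        y = self.y_flat[self.offsets[i]:self.offsets[i + 1]]
        t = self.t_flat[self.offsets[i]:self.offsets[i + 1]]
        return animal_loglik(
            y, t, bool(self.treated[i]), self.windowed, z_row, b,
            self.spec.error_model == "proportional", dt_max, self.lo, self.hi,
        )


@dataclass
class FitResult:
    """Converged population fit with likelihood, precision and EBE output."""

    theta_hat: Dict[str, float]
    omega_hat: Dict[str, float]
    b_hat: float
    loglik: float
    loglik_se: float
    bic: float
    rse: Dict[str, float]
    ebe: Dict[object, StructuralParams]
    shrinkage: Dict[str, float]
    convergence_trace: pd.DataFrame
    d: int
    n_obs: int
    spec: ModelSpec
    settings: SaemSettings
    fixed: Dict[str, float]
    _problem: _Problem = field(repr=False, default=None)
    _mu: np.ndarray = field(repr=False, default=None)
    _omega: np.ndarray = field(repr=False, default=None)
    _eta_hat: np.ndarray = field(repr=False, default=None)

    @property
    def eta_hat(self) -> pd.DataFrame:
        pr = self._problem
        rows = {}
        for k, p in enumerate(pr.params):
            col = np.full(pr.n, np.nan)
            col[p.animal_idx] = self._eta_hat[p.animal_idx, p.slot]
            rows[p.name] = col
        return pd.DataFrame(rows, index=pr.animals)

    def population(self) -> PopulationModel:
        """The fitted population law, usable for simulation (VPC etc.)."""
        pr = self._problem
        group_map: Dict[str, Dict[str, str]] = {a: {} for a in self.spec.control_arms if a in pr.arm_of.values()}
        for arm in pr.treated_arms:
            mapping = {}
            for p in pr.params:
                base = SLOTS[p.slot]
                if base in _TREAT_SLOTS and (
                    p.name == base or p.name == f"{base}_{arm}"
                ):
                    mapping[base] = p.name
            if self.spec.structural == "monotonic":
                mapping.setdefault("N_max", "_one")
                mapping.setdefault("t_norm1", "_one")
                mapping.setdefault("t_norm2", "_one")
            group_map[arm] = mapping
        theta = dict(self.theta_hat)
        omega = dict(self.omega_hat)
        if self.spec.structural == "monotonic":
            theta["_one"] = 1.0
            omega["_one"] = 0.0
        return PopulationModel(
            theta=theta,
            omega=omega,
            b=self.b_hat,
            group_map=group_map,
            error_model=self.spec.error_model,
        )


def compute_bic(loglik: float, n_obs: int, d: int) -> float:
    """Bayesian information criterion, -2*LL + ln(n)*d."""
    if n_obs < 1 or d < 1:
        raise ValueError("n_obs and d must be >= 1")
    return -2.0 * loglik + np.log(n_obs) * d


def _default_init(problem: _Problem, settings: SaemSettings) -> Dict[str, float]:
    """Starting values on the internal (transformed) scale.

    ``settings.init_theta`` overrides are given on the natural reporting
    scale (N_max, t_norm2 in days); they are converted to the internal
    window-length / amplitude-above-one parametrization here.
    """
    t0 = problem.t_flat.min()
    t_end = problem.t_flat.max()
    init = {
        "alpha_T": 0.15,
        "alpha_V": 0.1,
        "K": 2.0,
        "delta_V": 0.08,
        "N_max": 3.0,
        "t_norm1": t0 + 0.45 * (t_end - t0),
        "t_norm2": t0 + 0.70 * (t_end - t0),
        # geometric mean of the first observations
        "T0": float(np.exp(np.mean(np.log(problem.T0s)))),
    }
    natural = {}
    for p in problem.params:
        base = SLOTS[p.slot]
        natural[p.name] = settings.init_theta.get(
            p.name, settings.init_theta.get(base, init[base])
        )
    out = dict(natural)
    for p in problem.params:
        if SLOTS[p.slot] == "N_max":
            out[p.name] = max(natural[p.name] - 1.0, 0.05)
    for j1, j2 in problem.window_pairs:
        n1 = problem.params[j1].name
        n2 = problem.params[j2].name
        out[n2] = max(natural[n2] - natural[n1], 0.5)
    return out


def saem_fit(
    data: LongDataset,
    spec: ModelSpec,
    settings: Optional[SaemSettings] = None,
) -> FitResult:
    """Estimate the population model from a long-format dataset by SAEM."""
    settings = settings or SaemSettings()
    pr = _Problem(data, spec)
    prop_err = spec.error_model == "proportional"
    n_par = len(pr.params)

    init = _default_init(pr, settings)
    fixed_internal = {}
    for j, p in enumerate(pr.params):
        if p.theta_fixed is None:
            continue
        if SLOTS[p.slot] == "N_max":
            fixed_internal[j] = max(p.theta_fixed - 1.0, 1e-6)
        elif SLOTS[p.slot] == "t_norm2":
            raise NotImplementedError(
                "fixing t_norm2 directly is not supported; fix the window "
                "start and length via init instead"
            )
        else:
            fixed_internal[j] = p.theta_fixed
    mu = np.array([
        np.log(fixed_internal[j] if p.theta_fixed is not None else init[p.name])
        for j, p in enumerate(pr.params)
    ])
    omega = np.array([
        0.0 if p.theta_fixed is not None
        else (p.omega_fixed if p.omega_fixed is not None else settings.init_omega)
        for p in pr.params
    ])
    b = settings.init_b

    eta = np.zeros((settings.n_chains, pr.n, 8))
    steps = np.full((settings.n_chains, pr.n, 8), settings.step_init)
    s1 = np.zeros(n_par)
    s2 = np.zeros(n_par)
    s_rss = 0.0
    n_counts = np.array([len(p.animal_idx) for p in pr.params], dtype=float)

    n_iter = settings.n_burnin + settings.n_smooth
    trace_rows = []
    rng_base = int(settings.seed) % 2**31

    for k in range(n_iter):
        gamma = 1.0 if k < settings.n_burnin else 1.0 / (k - settings.n_burnin + 1)
        mu_mat = pr.mu_matrix(mu)
        omega_mat = pr.omega_matrix(omega)
        active = pr.active_matrix(omega)

        acc = np.zeros(8)
        prop_cnt = np.zeros(8)
        S1 = np.zeros(n_par)
        S2 = np.zeros(n_par)
        rss = 0.0
        for c in range(settings.n_chains):
            seed_kc = (rng_base * 7919 + k * settings.n_chains + c + 1) % 2**31
            a_c, p_c = mcmc_sweep(
                pr.y_flat, pr.t_flat, pr.offsets, pr.treated, pr.windowed,
                mu_mat, omega_mat, active, eta[c], b, prop_err, steps[c],
                settings.dt_max, seed_kc, pr.lo, pr.hi, settings.n_mcmc_passes,
            )
            acc += a_c
            prop_cnt += p_c
            z = mu_mat + eta[c]
            for j, p in enumerate(pr.params):
                zj = z[p.animal_idx, p.slot]
                S1[j] += zj.sum()
                S2[j] += (zj**2).sum()
            rss += residual_sumsq(
                pr.y_flat, pr.t_flat, pr.offsets, pr.treated, pr.windowed,
                mu_mat, eta[c], prop_err, settings.dt_max,
            )
        S1 /= settings.n_chains
        S2 /= settings.n_chains
        rss /= settings.n_chains

        # stochastic approximation of the sufficient statistics
        s1 += gamma * (S1 - s1)
        s2 += gamma * (S2 - s2)
        s_rss += gamma * (rss - s_rss)

        # M-step (exact for the log-normal/normal conjugate families).
        # Burn-in safeguards: IIV frozen for the first n_freeze iterations
        # while the fixed effects locate their basin, then released with a
        # simulated-annealing floor and a growth cap; the residual error has
        # the same floor plus a growth cap so one badly-mixed iteration
        # cannot flatten the likelihood.
        mu_prev = mu.copy()
        for j, p in enumerate(pr.params):
            if not p.estimated:
                continue
            mu[j] = np.clip(
                s1[j] / n_counts[j], np.log(pr.lo[p.slot]), np.log(pr.hi[p.slot])
            )
            if p.omega_fixed is None and k >= settings.n_freeze:
                w2 = max(s2[j] / n_counts[j] - mu[j] ** 2, 1e-8)
                if k < settings.n_burnin:
                    w2 = min(
                        max(w2, settings.anneal * omega[j] ** 2),
                        settings.omega_grow * omega[j] ** 2,
                    )
                omega[j] = min(np.sqrt(w2), settings.omega_max)

        b2 = max(s_rss / pr.n_obs, 1e-12)
        if k < settings.n_burnin:
            b2 = min(max(b2, settings.anneal * b**2), settings.b_grow * b**2)
        b = np.sqrt(b2)

        # recenter eta so each animal's phi is continuous across the M-step
        shift = mu_prev - mu
        for j, p in enumerate(pr.params):
            if shift[j] != 0.0:
                for c in range(settings.n_chains):
                    eta[c][p.animal_idx, p.slot] += shift[j]

        row = {"iteration": k, "phase": "burnin" if k < settings.n_burnin else "smoothing"}
        row.update(pr.report_theta(mu))
        for j, p in enumerate(pr.params):
            row[f"omega_{p.name}"] = omega[j]
        row["b"] = b
        trace_rows.append(row)

    if not np.all(np.isfinite(mu)) or not np.isfinite(b):
        raise RuntimeError(
            "SAEM diverged (non-finite estimates); see convergence trace"
        )

    theta_hat = pr.report_theta(mu)
    omega_hat = {p.name: float(omega[j]) for j, p in enumerate(pr.params) if p.estimated}
    d = (
        sum(1 for p in pr.params if p.estimated)
        + sum(1 for p in pr.params if p.omega_estimated)
        + 1
    )

    fixed = {p.name: p.theta_fixed for p in pr.params if p.theta_fixed is not None}
    fixed.update({f"omega_{p.name}": p.omega_fixed for p in pr.params
                  if p.estimated and p.omega_fixed is not None})

    fit = FitResult(
        theta_hat=theta_hat,
        omega_hat=omega_hat,
        b_hat=float(b),
        loglik=np.nan,
        loglik_se=np.nan,
        bic=np.nan,
        rse={},
        ebe={},
        shrinkage={},
        convergence_trace=pd.DataFrame(trace_rows),
        d=d,
        n_obs=pr.n_obs,
        spec=spec,
        settings=settings,
        fixed=fixed,
        _problem=pr,
        _mu=mu,
        _omega=omega,
    )
    fit._eta_warm = eta.mean(axis=0)

    _attach_ebe(fit)
    if settings.polish:
        _msl_polish(fit, settings.polish_draws, settings.seed + 29,
                    settings.polish_rounds, settings.polish_maxiter)
        fit._eta_warm = fit._eta_hat.copy()
        _attach_ebe(fit)
    if settings.compute_loglik:
        ll, se = loglik_importance(data, fit, settings.n_is_samples, settings.seed + 17)
        fit.loglik = ll
        fit.loglik_se = se
        fit.bic = compute_bic(ll, pr.n_obs, d)
    if settings.compute_rse:
        fit.rse = standard_errors(fit, data)
    return fit


# ---------------------------------------------------------------------------
# empirical Bayes estimates
# ---------------------------------------------------------------------------

def _map_eta(pr: _Problem, i: int, mu_mat, omega_mat, active, b: float,
             dt_max: float = 0.05, eta0: Optional[np.ndarray] = None
             ) -> Tuple[np.ndarray, bool]:
    """MAP estimate of one animal's eta; returns (eta_row, converged)."""
    idx = np.where(active[i])[0]
    if len(idx) == 0:
        return np.zeros(8), True
    w = omega_mat[i, idx]

    def nlp(x):
        z = mu_mat[i].copy()
        z[idx] += x
        ll = pr.loglik_animal(i, z, b, dt_max)
        if not np.isfinite(ll):
            return 1e10
        return -ll + 0.5 * np.sum((x / w) ** 2)

    x0 = eta0[idx] if eta0 is not None else np.zeros(len(idx))
    if not np.isfinite(nlp(x0)):
        x0 = np.zeros(len(idx))
    res = minimize(nlp, x0, method="L-BFGS-B",
                   options={"maxiter": 100, "ftol": 1e-11, "gtol": 1e-7})
    # polish: L-BFGS-B with FD gradients can stall on plateau edges
    res2 = minimize(nlp, res.x, method="Nelder-Mead",
                    options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 500})
    best = res2 if res2.fun <= res.fun else res
    eta_row = np.zeros(8)
    if np.isfinite(best.fun) and best.fun < 1e9:
        eta_row[idx] = best.x
    return eta_row, bool(np.isfinite(best.fun) and best.fun < 1e9)


def map_individual(
    data_i: pd.DataFrame,
    pop: PopulationModel,
    arm: Optional[str] = None,
    b: Optional[float] = None,
) -> Tuple[StructuralParams, Dict[str, float]]:
    """Empirical Bayes (MAP) estimate of one animal's parameters.

    ``data_i`` holds the animal's records (columns TIME, DV, and ARM unless
    ``arm`` is given).  Returns the MAP structural parameters and the eta
    estimates keyed by population-parameter name.  If the optimizer fails the
    prior mode (eta = 0) is returned with a warning.
    """
    if len(data_i) < 1:
        raise ValueError("need at least one observation")
    arm = arm or str(data_i["ARM"].iloc[0])
    frame = data_i.copy()
    frame["ID"] = "i"
    frame["ARM"] = arm
    data = LongDataset(frame[["ID", "TIME", "DV", "ARM"]])
    mapping = pop.group_map.get(arm)
    if mapping is None:
        raise KeyError(f"unknown arm {arm!r}")
    spec = ModelSpec(
        structural="transient" if mapping else "untreated",
        error_model=pop.error_model,
        control_arms=() if mapping else (arm,),
        fixed_omegas={},
    )
    pr = _Problem(data, spec)
    # impose the population's naming/values through the slot map; a
    # population without a T0 law conditions on the first observation
    mu = np.empty(len(pr.params))
    omega = np.empty(len(pr.params))
    for j, p in enumerate(pr.params):
        base = SLOTS[p.slot]
        name = mapping.get(base, base) if base in _TREAT_SLOTS else base
        if base == "T0" and "T0" not in pop.theta:
            mu[j] = np.log(pr.T0s[0])
            omega[j] = 0.0
        elif base == "N_max":
            mu[j] = np.log(max(pop.theta[name] - 1.0, 1e-3))
            omega[j] = pop.omega[name]
        elif base == "t_norm2":
            tn1_name = mapping["t_norm1"]
            mu[j] = np.log(max(pop.theta[name] - pop.theta[tn1_name], 0.5))
            omega[j] = pop.omega[name]
        else:
            mu[j] = np.log(pop.theta[name])
            omega[j] = pop.omega[name]
        p.name = name
    mu_mat = pr.mu_matrix(mu)
    omega_mat = pr.omega_matrix(omega)
    active = pr.active_matrix(omega)
    b = pop.b if b is None else b
    eta_row, ok = _map_eta(pr, 0, mu_mat, omega_mat, active, b)
    if not ok:
        warnings.warn("individual MAP optimization failed; returning eta = 0")
        eta_row = np.zeros(8)
    phi = pr.phi_of(mu_mat[0] + eta_row, bool(pr.treated[0]))
    params = StructuralParams(
        alpha_T=phi[0], alpha_V=phi[1], K=phi[2],
        delta_V=phi[3] if pr.treated[0] else 0.0,
        N_max=phi[4] if pr.treated[0] else 1.0,
        t_norm1=phi[5] if pr.treated[0] else 0.0,
        t_norm2=phi[6] if pr.treated[0] else 0.0,
        T0=phi[7],
    )
    etas = {p.name: float(eta_row[p.slot]) for p in pr.params}
    return params, etas


def _attach_ebe(fit: FitResult) -> None:
    pr = fit._problem
    mu_mat = pr.mu_matrix(fit._mu)
    omega_mat = pr.omega_matrix(fit._omega)
    active = pr.active_matrix(fit._omega)
    eta_hat = np.zeros((pr.n, 8))
    ebe = {}
    warm = getattr(fit, "_eta_warm", None)
    for i, animal in enumerate(pr.animals):
        eta_hat[i], ok = _map_eta(pr, i, mu_mat, omega_mat, active, fit.b_hat,
                                  dt_max=fit.settings.dt_max,
                                  eta0=None if warm is None else warm[i])
        if not ok:
            warnings.warn(f"EBE optimization failed for animal {animal!r}")
        phi = pr.phi_of(mu_mat[i] + eta_hat[i], bool(pr.treated[i]))
        ebe[animal] = StructuralParams(
            alpha_T=phi[0], alpha_V=phi[1], K=phi[2],
            delta_V=phi[3] if pr.treated[i] else 0.0,
            N_max=phi[4] if pr.treated[i] else 1.0,
            t_norm1=phi[5] if pr.treated[i] else 0.0,
            t_norm2=phi[6] if pr.treated[i] else 0.0,
            T0=phi[7],
        )
    fit._eta_hat = eta_hat
    fit.ebe = ebe

    shr = {}
    for j, p in enumerate(fit._problem.params):
        w = fit._omega[j]
        if not p.estimated or w <= 0:
            continue
        e = eta_hat[p.animal_idx, p.slot]
        if len(e) >= 2:
            shr[p.name] = float(1.0 - np.var(e, ddof=1) / w**2)
    fit.shrinkage = shr


# ---------------------------------------------------------------------------
# marginal log-likelihood by importance sampling
# ---------------------------------------------------------------------------

def _posterior_cov(pr: _Problem, i: int, mu_mat, omega_mat, active, eta_row,
                   b: float, dt_max: float = 0.05) -> np.ndarray:
    """Inverse-Hessian covariance of eta at the MAP, with prior fallback."""
    idx = np.where(active[i])[0]
    w = omega_mat[i, idx]
    x0 = eta_row[idx]
    m = len(idx)

    def nlp(x):
        z = mu_mat[i].copy()
        z[idx] += x
        return -pr.loglik_animal(i, z, b, dt_max) + 0.5 * np.sum((x / w) ** 2)

    h = 1e-3
    H = np.zeros((m, m))
    with np.errstate(invalid="ignore"):
        for a in range(m):
            for c in range(a, m):
                ea = np.zeros(m); ea[a] = h
                ec = np.zeros(m); ec[c] = h
                H[a, c] = H[c, a] = (
                    nlp(x0 + ea + ec) - nlp(x0 + ea - ec)
                    - nlp(x0 - ea + ec) + nlp(x0 - ea - ec)
                ) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
        if not np.all(np.isfinite(cov)) or np.any(np.linalg.eigvalsh(cov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.diag(w**2)
    return cov


def loglik_importance(
    data: LongDataset,
    fit: FitResult,
    n_is_samples: int = 1000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Monte-Carlo estimate of the marginal log-likelihood.

    For each animal the random effects are integrated out by defensive
    importance sampling: half the draws come from a Gaussian centered at the
    animal's MAP eta with (inflated) inverse-Hessian covariance, half from
    the population prior itself, and the proposal density is the mixture of
    the two.  Because the mixture dominates the prior, the weights
    p(y|eta) p(eta) / q(eta) are bounded by twice the conditional likelihood,
    so the estimator has finite variance even when the Hessian component is
    badly scaled.  Returns (log-likelihood, Monte-Carlo SE).
    """
    pr = fit._problem
    mu_mat = pr.mu_matrix(fit._mu)
    omega_mat = pr.omega_matrix(fit._omega)
    active = pr.active_matrix(fit._omega)
    rng = np.random.default_rng(int(seed) % 2**31)
    total = 0.0
    var_total = 0.0
    for i in range(pr.n):
        idx = np.where(active[i])[0]
        if len(idx) == 0:
            total += pr.loglik_animal(i, mu_mat[i], fit.b_hat)
            continue
        m_dim = len(idx)
        w = omega_mat[i, idx]
        center = fit._eta_hat[i, idx]
        cov = _posterior_cov(pr, i, mu_mat, omega_mat, active, fit._eta_hat[i], fit.b_hat)
        L1 = np.linalg.cholesky(1.5**2 * cov + 1e-10 * np.eye(m_dim))
        n1 = n_is_samples // 2
        n2 = n_is_samples - n1
        x1 = center + rng.standard_normal((n1, m_dim)) @ L1.T
        x2 = rng.standard_normal((n2, m_dim)) * w
        x = np.vstack([x1, x2])
        logq1 = _mvn_logpdf(x - center, L1)
        logq2 = _diag_logpdf(x, w)
        logq = np.logaddexp(logq1, logq2) - np.log(2.0)
        logp_prior = _diag_logpdf(x, w)
        Z = np.tile(mu_mat[i], (n_is_samples, 1))
        Z[:, idx] += x
        logl = batch_loglik(
            pr.y_flat[pr.offsets[i]:pr.offsets[i + 1]],
            pr.t_flat[pr.offsets[i]:pr.offsets[i + 1]],
            bool(pr.treated[i]), pr.windowed, Z, fit.b_hat,
            fit.spec.error_model == "proportional",
            fit.settings.dt_max, pr.lo, pr.hi,
        )
        logw = logl + logp_prior - logq
        m = np.max(logw)
        wgt = np.exp(logw - m)
        total += m + np.log(np.mean(wgt))
        var_total += np.var(wgt) / (np.mean(wgt) ** 2 * n_is_samples)
    return float(total), float(np.sqrt(var_total))


def _msl_polish(fit: FitResult, n_draws: int = 500, seed: int = 0,
                rounds: int = 4, maxiter: int = 20, trust: float = 0.4) -> None:
    """Iterated maximum-simulated-likelihood refinement of the population fit.

    The marginal likelihood of this model is extremely flat along a ridge
    coupling the growth rate, the window amplitude and the vessel kill
    rates, and the stochastic-EM equilibrium can settle anywhere on it.
    Each refinement round (i) recomputes the per-animal MAP random effects
    and freezes one set of defensive importance-sampling draws at the
    current estimate, making the simulated marginal log-likelihood a smooth
    deterministic function of (theta, omega, b); and (ii) ascends it with a
    bound-constrained quasi-Newton step restricted to a trust region within
    which the frozen proposals remain valid.  Re-anchoring the draws between
    rounds lets the estimate travel along the ridge toward the maximum
    instead of being pinned where the proposals were first drawn.  Updates
    the fit in place.
    """
    pr = fit._problem
    prop_err = fit.spec.error_model == "proportional"
    rng = np.random.default_rng(int(seed) % 2**31)
    ys = [pr.y_flat[pr.offsets[i]:pr.offsets[i + 1]] for i in range(pr.n)]
    ts = [pr.t_flat[pr.offsets[i]:pr.offsets[i + 1]] for i in range(pr.n)]
    est = [j for j, p in enumerate(pr.params) if p.estimated]
    west = [j for j, p in enumerate(pr.params) if p.omega_estimated]
    n_mu, n_w = len(est), len(west)
    # a coarse integration grid is ample here (relative error ~1e-6) and
    # keeps the many likelihood evaluations cheap
    dt = max(fit.settings.dt_max, 1.0)

    for _ in range(rounds):
        mu_mat = pr.mu_matrix(fit._mu)
        omega_mat = pr.omega_matrix(fit._omega)
        active = pr.active_matrix(fit._omega)
        eta_map = np.zeros((pr.n, 8))
        draws = []   # per animal: (idx, x, logq)
        for i in range(pr.n):
            idx = np.where(active[i])[0]
            if len(idx) == 0:
                draws.append((idx, None, None))
                continue
            m_dim = len(idx)
            w = omega_mat[i, idx]
            eta_i, _ = _map_eta(pr, i, mu_mat, omega_mat, active, fit.b_hat,
                                dt_max=dt,
                                eta0=fit._eta_hat[i] if fit._eta_hat is not None else None)
            eta_map[i] = eta_i
            center = eta_i[idx]
            cov = _posterior_cov(pr, i, mu_mat, omega_mat, active, eta_i,
                                 fit.b_hat, dt_max=dt)
            L1 = np.linalg.cholesky(1.5**2 * cov + 1e-10 * np.eye(m_dim))
            n1 = n_draws // 2
            x1 = center + rng.standard_normal((n1, m_dim)) @ L1.T
            x2 = rng.standard_normal((n_draws - n1, m_dim)) * w
            x = np.vstack([x1, x2])
            logq = np.logaddexp(
                _mvn_logpdf(x - center, L1), _diag_logpdf(x, w)
            ) - np.log(2.0)
            draws.append((idx, x, logq))

        # clamp the current point into the global boxes so the trust region
        # is always non-empty
        for j in est:
            fit._mu[j] = np.clip(fit._mu[j], np.log(pr.lo[pr.params[j].slot]),
                                 np.log(pr.hi[pr.params[j].slot]))
        fit._omega[west] = np.clip(fit._omega[west], 0.01, 2.0)
        fit.b_hat = float(np.clip(fit.b_hat, 1.5e-3, 1.9))
        p0 = np.concatenate([
            fit._mu[est], np.log(fit._omega[west]), [np.log(fit.b_hat)]
        ])
        bounds = [
            (
                max(fit._mu[j] - trust, np.log(pr.lo[pr.params[j].slot])),
                min(fit._mu[j] + trust, np.log(pr.hi[pr.params[j].slot])),
            )
            for j in est
        ] + [
            (
                max(np.log(fit._omega[j]) - trust, np.log(0.01)),
                min(np.log(fit._omega[j]) + trust, np.log(2.0)),
            )
            for j in west
        ] + [
            (np.log(fit.b_hat) - trust, min(np.log(fit.b_hat) + trust, np.log(2.0)))
        ]

        def neg_sll(pvec):
            mu = fit._mu.copy()
            mu[est] = pvec[:n_mu]
            om = fit._omega.copy()
            om[west] = np.exp(pvec[n_mu:n_mu + n_w])
            b = np.exp(pvec[-1])
            mu_m = pr.mu_matrix(mu)
            om_m = pr.omega_matrix(om)
            total = 0.0
            for i in range(pr.n):
                idx, x, logq = draws[i]
                if x is None:
                    total += pr.loglik_animal(i, mu_m[i], b, dt_max=dt)
                    continue
                Z = np.tile(mu_m[i], (x.shape[0], 1))
                Z[:, idx] += x
                logl = batch_loglik(
                    ys[i], ts[i], bool(pr.treated[i]), pr.windowed, Z, b,
                    prop_err, dt, pr.lo, pr.hi,
                )
                logw = logl + _diag_logpdf(x, om_m[i, idx]) - logq
                m = np.max(logw)
                if not np.isfinite(m):
                    return 1e10
                total += m + np.log(np.mean(np.exp(logw - m)))
            return -total

        fit._eta_hat = eta_map
        res = minimize(neg_sll, p0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-9})
        if not np.isfinite(res.fun) or res.fun >= 1e9:
            break
        step = np.max(np.abs(res.x - p0))
        fit._mu[est] = res.x[:n_mu]
        fit._omega[west] = np.exp(res.x[n_mu:n_mu + n_w])
        fit.b_hat = float(np.exp(res.x[-1]))
        fit.theta_hat = pr.report_theta(fit._mu)
        for col, j in enumerate(west):
            fit.omega_hat[pr.params[j].name] = float(fit._omega[j])
        if step < 0.01:
            break


def population_fit(
    data: LongDataset,
    spec: ModelSpec,
    theta: Dict[str, float],
    omega: Dict[str, float],
    b: float,
) -> FitResult:
    """A FitResult pinned at a given population law (no estimation).

    ``theta`` is given on the natural reporting scale (N_max, t_norm2 in
    days).  Empirical Bayes estimates are attached, so all diagnostics
    (CWRES, VPC, observed-vs-predicted) can be evaluated at an externally
    specified population — e.g. at the generating truth of a simulation.
    """
    pr = _Problem(data, spec)
    internal = dict(theta)
    for p in pr.params:
        if SLOTS[p.slot] == "N_max":
            internal[p.name] = max(theta[p.name] - 1.0, 1e-3)
    for j1, j2 in pr.window_pairs:
        n1, n2 = pr.params[j1].name, pr.params[j2].name
        internal[n2] = max(theta[n2] - theta[n1], 0.5)
    mu = np.array([np.log(internal[p.name]) for p in pr.params])
    om = np.array([omega.get(p.name, 0.0) for p in pr.params])
    fit = FitResult(
        theta_hat=pr.report_theta(mu),
        omega_hat={p.name: float(om[j]) for j, p in enumerate(pr.params)},
        b_hat=float(b), loglik=np.nan, loglik_se=np.nan, bic=np.nan,
        rse={}, ebe={}, shrinkage={}, convergence_trace=pd.DataFrame(),
        d=0, n_obs=pr.n_obs, spec=spec, settings=SaemSettings(),
        fixed={}, _problem=pr, _mu=mu, _omega=om,
    )
    _attach_ebe(fit)
    return fit


def evaluate_loglik(
    data: LongDataset,
    spec: ModelSpec,
    theta: Dict[str, float],
    omega: Dict[str, float],
    b: float,
    n_is_samples: int = 2000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Marginal log-likelihood of the data at a given population law.

    Builds the estimation problem for ``spec``, computes per-animal MAP
    random effects, and integrates them out by the same defensive
    importance-sampling scheme used after a fit.  Useful for comparing
    candidate population parameter sets on equal footing.
    """
    fit = population_fit(data, spec, theta, omega, b)
    return loglik_importance(data, fit, n_is_samples, seed)


def _mvn_logpdf(dx: np.ndarray, L: np.ndarray) -> np.ndarray:
    u = solve_triangular(L, dx.T, lower=True)
    return (
        -0.5 * np.sum(u**2, axis=0)
        - np.sum(np.log(np.diag(L)))
        - 0.5 * dx.shape[1] * np.log(2 * np.pi)
    )


def _diag_logpdf(x: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (
        -0.5 * np.sum((x / sd) ** 2, axis=1)
        - np.sum(np.log(sd))
        - 0.5 * x.shape[1] * np.log(2 * np.pi)
    )


# ---------------------------------------------------------------------------
# standard errors by first-order linearization
# ---------------------------------------------------------------------------

def _design_gradients(pr: _Problem, mu_mat, dt_max: float = 0.05):
    """Per-animal Jacobians df/dz at eta = 0 (central differences)."""
    grads = []
    preds = []
    h = 1e-4
    for i in range(pr.n):
        idx = np.where(pr.slot_map[i] >= 0)[0]
        f0 = pr.predict_animal(i, mu_mat[i], dt_max)
        F = np.zeros((len(f0), 8))
        for j in idx:
            zp = mu_mat[i].copy(); zp[j] += h
            zm = mu_mat[i].copy(); zm[j] -= h
            F[:, j] = (pr.predict_animal(i, zp, dt_max) - pr.predict_animal(i, zm, dt_max)) / (2 * h)
        grads.append(F)
        preds.append(f0)
    return grads, preds


def standard_errors(fit: FitResult, data: Optional[LongDataset] = None) -> Dict[str, float]:
    """RSE (%) of the population estimates via the linearized Fisher information.

    The conditional model is linearized around eta = 0 (first-order
    approximation): y_i ~ N(f_i, F_i Omega_i F_i' + R_i) with R_i the
    residual-error covariance.  Fixed parameters are excluded.  A singular
    information matrix yields NaN entries with a warning.
    """
    pr = fit._problem
    mu_mat = pr.mu_matrix(fit._mu)
    omega_mat = pr.omega_matrix(fit._omega)
    prop_err = fit.spec.error_model == "proportional"
    grads, preds = _design_gradients(pr, mu_mat)

    est_mu = [j for j, p in enumerate(pr.params) if p.estimated]
    est_w = [j for j, p in enumerate(pr.params) if p.omega_estimated]
    n_mu, n_w = len(est_mu), len(est_w)
    dim = n_mu + n_w + 1
    FIM = np.zeros((dim, dim))

    for i in range(pr.n):
        F = grads[i]
        f0 = preds[i]
        ni = len(f0)
        Om = np.diag(omega_mat[i] ** 2)
        R = np.diag((fit.b_hat * f0) ** 2) if prop_err else fit.b_hat**2 * np.eye(ni)
        Sigma = F @ Om @ F.T + R
        Si = np.linalg.inv(Sigma)

        G = np.zeros((ni, n_mu))
        for col, j in enumerate(est_mu):
            p = pr.params[j]
            if pr.slot_map[i, p.slot] == j:
                G[:, col] = F[:, p.slot]
        FIM[:n_mu, :n_mu] += G.T @ Si @ G

        dSigmas = []
        for j in est_w:
            p = pr.params[j]
            if pr.slot_map[i, p.slot] == j:
                fj = F[:, p.slot]
                dSigmas.append(np.outer(fj, fj))
            else:
                dSigmas.append(None)
        dR = np.diag(f0**2) if prop_err else np.eye(ni)
        dSigmas.append(dR)  # d Sigma / d b^2
        for a, Da in enumerate(dSigmas):
            if Da is None:
                continue
            SDa = Si @ Da
            for c, Dc in enumerate(dSigmas[a:], start=a):
                if Dc is None:
                    continue
                val = 0.5 * np.trace(SDa @ Si @ Dc)
                FIM[n_mu + a, n_mu + c] += val
                if c != a:
                    FIM[n_mu + c, n_mu + a] += val

    rse: Dict[str, float] = {}
    try:
        cov = np.linalg.inv(FIM)
        if np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular Fisher information; RSE set to NaN")
        for j in est_mu:
            rse[pr.params[j].name] = np.nan
        for j in est_w:
            rse[f"omega_{pr.params[j].name}"] = np.nan
        rse["b"] = np.nan
        return rse

    se = np.sqrt(np.diag(cov))
    col_of = {j: col for col, j in enumerate(est_mu)}
    for col, j in enumerate(est_mu):
        # theta = exp(mu): SE(mu) is already the relative SE of theta
        rse[pr.params[j].name] = float(100.0 * se[col])
    # delta method for the derived reporting scales: N_max = 1 + exp(mu),
    # t_norm2 = t_norm1 + window length
    for j in est_mu:
        p = pr.params[j]
        if SLOTS[p.slot] == "N_max":
            g = np.exp(fit._mu[j])
            rse[p.name] = float(100.0 * g * se[col_of[j]] / (1.0 + g))
    for j1, j2 in pr.window_pairs:
        if j1 in col_of and j2 in col_of:
            t1 = np.exp(fit._mu[j1])
            gap = np.exp(fit._mu[j2])
            c1, c2 = col_of[j1], col_of[j2]
            var = (t1 * se[c1]) ** 2 + (gap * se[c2]) ** 2 \
                + 2.0 * t1 * gap * cov[c1, c2]
            rse[pr.params[j2].name] = float(
                100.0 * np.sqrt(max(var, 0.0)) / (t1 + gap)
            )
    for col, j in enumerate(est_w):
        wv = fit._omega[j]
        se_w = se[n_mu + col] / (2.0 * wv)  # delta method omega^2 -> omega
        rse[f"omega_{pr.params[j].name}"] = float(100.0 * se_w / wv)
    se_b = se[-1] / (2.0 * fit.b_hat)
    rse["b"] = float(100.0 * se_b / fit.b_hat)
    return rse
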