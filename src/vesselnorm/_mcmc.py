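"""Numba kernels for the stochastic E-step of the SAEM algorithm.

One animal's random effects are updated by a Metropolis-Hastings pass with
two kernels: an independence proposal from the current population law (good
global moves early on) and a componentwise random walk whose step sizes are
adapted outside this module to target ~30% acceptance.  All individual
parameters live on the log scale, so the prior on each eta component is a
centered normal with the population IIV standard deviation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._ode import predict_T

LOG2PI = np.log(2.0 * np.pi)


@njit(cache=True)
def animal_loglik(y, times, treated, windowed, z, b, prop_err, dt_max, lo, hi):
    """log p(y | z) for one animal; z = log individual parameters.

    ``z`` has 8 components: (alpha_T, alpha_V, K, delta_V, N_max - 1,
    t_norm1, window length, T0), all log-normal.  Estimating the window
    amplitude above its baseline of 1 and the window length (rather than
    N_max and t_norm2 directly) builds the constraints N >= 1 and
    t_norm1 < t_norm2 into the parametrization, so the individual priors
    need no truncation beyond the physiological box [lo, hi]; out-of-box
    states score -inf.  ``windowed`` is false for the monotonic structural
    model, whose treated animals have a vessel-kill rate but no window.
    """
    phi = np.exp(z)
    for j in range(3):
        if not (lo[j] <= phi[j] <= hi[j]):
            return -np.inf
    if not (lo[7] <= phi[7] <= hi[7]):
        return -np.inf
    if treated:
        if not (lo[3] <= phi[3] <= hi[3]):
            return -np.inf
        phi = phi.copy()
        if windowed:
            for j in range(4, 7):
                if not (lo[j] <= phi[j] <= hi[j]):
                    return -np.inf
            # window must end within the observation horizon
            if phi[5] + phi[6] > hi[5]:
                return -np.inf
            phi[4] = 1.0 + phi[4]
            phi[6] = phi[5] + phi[6]
        else:
            phi[4] = 1.0
            phi[5] = -1.0
            phi[6] = -1.0
    f = predict_T(times, phi[7], phi, treated, dt_max)
    ll = 0.0
    for j in range(y.shape[0]):
        fj = f[j]
        if not np.isfinite(fj) or fj <= 0.0:
            return -np.inf
        sd = b * fj if prop_err else b
        r = (y[j] - fj) / sd
        ll += -0.5 * r * r - np.log(sd) - 0.5 * LOG2PI
    return ll


@njit(cache=True)
def mcmc_sweep(
    y_flat,
    t_flat,
    offsets,
    treated,
    windowed,
    mu_mat,
    omega_mat,
    active,
    eta,
    b,
    prop_err,
    steps,
    dt_max,
    seed,
    lo,
    hi,
    n_passes,
):
    """Metropolis passes over all animals; updates ``eta`` in place.

    ``steps`` is a per-(animal, component) random-walk scale, adapted in
    place by a Robbins-Monro rule targeting ~30% acceptance.  Returns
    per-slot (acceptances, proposals) for monitoring.
    """
    np.random.seed(seed)
    n = offsets.shape[0] - 1
    acc = np.zeros(8)
    prop_cnt = np.zeros(8)
    for i in range(n):
        y = y_flat[offsets[i]:offsets[i + 1]]
        t = t_flat[offsets[i]:offsets[i + 1]]
        ll = animal_loglik(y, t, treated[i], windowed, mu_mat[i] + eta[i], b, prop_err, dt_max, lo, hi)

        for _ in range(n_passes):
            # kernel 1: independence proposal from the prior N(0, omega^2)
            eta_star = np.zeros(8)
            for j in range(8):
                if active[i, j]:
                    eta_star[j] = omega_mat[i, j] * np.random.normal()
            ll_star = animal_loglik(y, t, treated[i], windowed, mu_mat[i] + eta_star, b, prop_err, dt_max, lo, hi)
            if np.log(np.random.random()) < ll_star - ll:
                for j in range(8):
                    eta[i, j] = eta_star[j]
                ll = ll_star

            # kernel 2: componentwise adaptive random walk
            for j in range(8):
                if active[i, j]:
                    old = eta[i, j]
                    eta[i, j] = old + steps[i, j] * np.random.normal()
                    ll_star = animal_loglik(
                        y, t, treated[i], windowed, mu_mat[i] + eta[i], b, prop_err, dt_max, lo, hi
                    )
                    w2 = omega_mat[i, j] ** 2
                    dprior = -0.5 * (eta[i, j] ** 2 - old * old) / w2
                    prop_cnt[j] += 1.0
                    if np.log(np.random.random()) < ll_star - ll + dprior:
                        ll = ll_star
                        acc[j] += 1.0
                        steps[i, j] *= 1.15
                    else:
                        eta[i, j] = old
                        steps[i, j] *= 0.942
                    if steps[i, j] < 1e-4:
                        steps[i, j] = 1e-4
                    elif steps[i, j] > 2.0:
                        steps[i, j] = 2.0
    return acc, prop_cnt


@njit(cache=True)
def batch_loglik(y, times, treated, windowed, Z, b, prop_err, dt_max, lo, hi):
    """log p(y | z_s) for one animal over a batch of parameter vectors."""
    S = Z.shape[0]
    out = np.empty(S)
    for s in range(S):
        out[s] = animal_loglik(y, times, treated, windowed, Z[s], b, prop_err, dt_max, lo, hi)
    return out


@njit(cache=True)
def residual_sumsq(y_flat, t_flat, offsets, treated, windowed, mu_mat, eta, prop_err, dt_max):
    """Sum of squared (weighted) residuals at the current individual draws."""
    n = offsets.shape[0] - 1
    rss = 0.0
    for i in range(n):
        y = y_flat[offsets[i]:offsets[i + 1]]
        t = t_flat[offsets[i]:offsets[i + 1]]
        phi = np.exp(mu_mat[i] + eta[i])
        if treated[i]:
            phi = phi.copy()
            if windowed:
                phi[4] = 1.0 + phi[4]
                phi[6] = phi[5] + phi[6]
            else:
                phi[4] = 1.0
                phi[5] = -1.0
                phi[6] = -1.0
        f = predict_T(t, phi[7], phi, treated[i], dt_max)
        for j in range(y.shape[0]):
            fj = f[j] if f[j] > 1e-300 else 1e-300
            r = (y[j] - fj) / fj if prop_err else (y[j] - fj)
            rss += r * r
    return rss
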