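"""Fast fixed-step integrator for the vascular tumor growth ODEs.

This is the numerical workhorse behind the mixed-effects machinery, where the
two-state system has to be solved tens of thousands of times per fit.  It is a
classical fourth-order Runge-Kutta scheme on a grid that is forced to land
exactly on every discontinuity of the right-hand side (window boundaries,
chemotherapy on/off switches, and the integer-day resets of the intra-day drug
decay), so no step ever straddles a jump.  The public, adaptive integration
path lives in :mod:`vesselnorm.models`; the two are cross-checked in the test
suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: positivity floor for states appearing under fractional powers (mm^3)
STATE_FLOOR = 1e-12


@njit(cache=True, inline="always")
def _deriv(t, T, V, aT, aV, dV, N, chemo_on, aC, kdec, dT_kill, lam, day0, tcon):
    Ts = T if T > STATE_FLOOR else STATE_FLOOR
    Vs = V if V > STATE_FLOOR else STATE_FLOOR
    cap = N * Vs
    if cap < STATE_FLOOR:
        cap = STATE_FLOOR
    dTdt = aT * T * (1.0 - T / cap)
    dVdt = aV * Ts ** (2.0 / 3.0) * Vs ** (1.0 / 3.0) - dV * V
    if chemo_on:
        # capacity volume in ml for the delivery term (1 mm^3 = 1e-3 ml)
        C = aC * N * Vs * 1e-3 * np.exp(-kdec * (t - day0))
        # resistance emerges with drug exposure: clock starts at chemo onset
        dTdt -= dT_kill * C * T * np.exp(-lam * (t - tcon))
    return dTdt, dVdt


@njit(cache=True)
def integrate(
    times,
    T0,
    V0,
    aT,
    aV,
    dV,
    Nmax,
    tn1,
    tn2,
    use_chemo,
    aC,
    kdec,
    dT_kill,
    lam,
    tcon,
    tcoff,
    dt_max,
):
    """Integrate T(t), V(t) from ``times[0]`` and return values at ``times``.

    ``times`` must be strictly increasing.  The untreated model is obtained
    with ``dV = 0`` and ``Nmax = 1``; the chemotherapy kill term is only
    active when ``use_chemo`` is true.
    """
    n_out = times.shape[0]
    t0 = times[0]
    t_end = times[n_out - 1]

    # --- assemble breakpoints: output times + every RHS discontinuity -----
    n_days = 0
    if use_chemo:
        d0 = int(np.ceil(tcon))
        d1 = int(np.floor(tcoff))
        if float(d0) == tcon:
            d0 += 1
        n_days = max(0, d1 - d0 + 1)
    cand = np.empty(n_out + 4 + n_days)
    m = 0
    for i in range(n_out):
        cand[m] = times[i]
        m += 1
    cand[m] = tn1
    m += 1
    cand[m] = tn2
    m += 1
    if use_chemo:
        cand[m] = tcon
        m += 1
        cand[m] = tcoff
        m += 1
        for d in range(n_days):
            cand[m] = float(d0 + d)
            m += 1
    cand = cand[:m]
    # clip to the horizon, sort, dedupe
    keep = np.empty(m)
    k = 0
    for i in range(m):
        if t0 - 1e-12 <= cand[i] <= t_end + 1e-12:
            keep[k] = cand[i]
            k += 1
    bpts = np.sort(keep[:k])
    uniq = np.empty(k)
    u = 0
    for i in range(k):
        if u == 0 or bpts[i] - uniq[u - 1] > 1e-9:
            uniq[u] = bpts[i]
            u += 1
    bpts = uniq[:u]

    T_out = np.empty(n_out)
    V_out = np.empty(n_out)
    T = T0
    V = V0
    out_idx = 0
    if abs(bpts[0] - t0) < 1e-9 and abs(times[0] - t0) < 1e-9:
        T_out[0] = T
        V_out[0] = V
        out_idx = 1

    for s in range(u - 1):
        a = bpts[s]
        b = bpts[s + 1]
        tmid = 0.5 * (a + b)
        N = Nmax if (tn1 < tmid < tn2) else 1.0
        chemo_on = use_chemo and (tcon < tmid < tcoff)
        # phase reference for the intra-day decay: start of the current day
        day0 = np.floor(a + 1e-9)
        n_sub = int(np.ceil((b - a) / dt_max))
        if n_sub < 1:
            n_sub = 1
        h = (b - a) / n_sub
        t = a
        for _ in range(n_sub):
            k1T, k1V = _deriv(t, T, V, aT, aV, dV, N, chemo_on, aC, kdec, dT_kill, lam, day0, tcon)
            k2T, k2V = _deriv(
                t + 0.5 * h, T + 0.5 * h * k1T, V + 0.5 * h * k1V,
                aT, aV, dV, N, chemo_on, aC, kdec, dT_kill, lam, day0, tcon,
            )
            k3T, k3V = _deriv(
                t + 0.5 * h, T + 0.5 * h * k2T, V + 0.5 * h * k2V,
                aT, aV, dV, N, chemo_on, aC, kdec, dT_kill, lam, day0, tcon,
            )
            k4T, k4V = _deriv(
                t + h, T + h * k3T, V + h * k3V,
                aT, aV, dV, N, chemo_on, aC, kdec, dT_kill, lam, day0, tcon,
            )
            T = T + (h / 6.0) * (k1T + 2.0 * k2T + 2.0 * k3T + k4T)
            V = V + (h / 6.0) * (k1V + 2.0 * k2V + 2.0 * k3V + k4V)
            if T < STATE_FLOOR:
                T = STATE_FLOOR
            if V < STATE_FLOOR:
                V = STATE_FLOOR
            t = t + h
        while out_idx < n_out and abs(times[out_idx] - b) < 1e-9:
            T_out[out_idx] = T
            V_out[out_idx] = V
            out_idx += 1
    return T_out, V_out


@njit(cache=True)
def predict_T(times, T0, phi, treated, dt_max):
    """Tumor-volume predictions for one animal from its parameter vector.

    ``phi`` holds (alpha_T, alpha_V, K, delta_V, N_max, t_norm1, t_norm2) on
    the natural scale; ``treated`` selects whether the vessel-kill and window
    terms are active (control animals run the reduction delta_V=0, N=1).
    """
    aT = phi[0]
    aV = phi[1]
    K = phi[2]
    if treated:
        dV = phi[3]
        Nmax = phi[4]
        tn1 = phi[5]
        tn2 = phi[6]
    else:
        dV = 0.0
        Nmax = 1.0
        tn1 = -1.0
        tn2 = -1.0
    T, _ = integrate(
        times, T0, K * T0, aT, aV, dV, Nmax, tn1, tn2,
        False, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, dt_max,
    )
    return T
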