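"""Structural models of vascular tumor growth under antiangiogenic therapy.

The tumor volume ``T`` (mm^3) grows logistically toward a vessel-dependent
carrying capacity ``V`` (mm^3), itself a dynamic state driven by the tumor
surface area (Hahnfeldt-style stimulation, exponents beta=2/3, gamma=1/3).
Antiangiogenic treatment prunes vessels at rate ``delta_V`` and opens a
transient normalization window (t_norm1, t_norm2) during which the effective
carrying capacity is multiplied by ``N_max`` — the model's representation of
transiently improved perfusion.  A combination-therapy variant adds a
chemotherapy kill term whose intratumoral concentration is algebraic (drug
delivery proportional to N*V, intra-day exponential decay, emerging
resistance).

Three structural variants are exposed:

``untreated``
    logistic tumor growth + vessel-stimulated capacity growth only;
``treated``
    adds vessel kill ``-delta_V*V`` and the normalization window ``N(t)``;
``combo``
    adds the chemotherapy kill term ``-delta_T*C*T*exp(-lambda*t)``.

``simulate_individual`` integrates the chosen variant with an adaptive
stiff-capable solver restarted at every discontinuity of the right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._ode import STATE_FLOOR

__all__ = [
    "StructuralParams",
    "ChemoParams",
    "Trajectory",
    "normalization_factor",
    "rhs_untreated",
    "rhs_treated",
    "chemo_concentration",
    "rhs_combo",
    "simulate_individual",
]


@dataclass
class StructuralParams:
    """One individual's structural-model constants.

    Parameters
    ----------
    alpha_T : float
        Maximal tumor growth rate (day^-1).
    alpha_V : float
        Growth rate of the vessel-dependent carrying capacity (day^-1).
    K : float
        Initial ratio of carrying capacity to tumor volume, V0 = K * T0
        (dimensionless).
    delta_V : float
        Vessel kill rate under antiangiogenic treatment (day^-1).
    N_max : float
        Maximum factor by which the carrying capacity is enhanced inside the
        normalization window (dimensionless, >= 0).
    t_norm1, t_norm2 : float
        Start and end of the normalization window (days).
    beta, gamma : float
        Capacity-stimulation exponents, fixed at 2/3 and 1/3 on geometric
        grounds (hypoxic fraction ~ surface area; exponential vessel growth
        at long times requires beta + gamma = 1).
    T0 : float
        Initial tumor volume (mm^3) at the first observation day.
    """

    alpha_T: float
    alpha_V: float
    K: float
    delta_V: float = 0.0
    N_max: float = 1.0
    t_norm1: float = 0.0
    t_norm2: float = 0.0
    beta: float = 2.0 / 3.0
    gamma: float = 1.0 / 3.0
    T0: float = 70.0

    def __post_init__(self) -> None:
        if self.alpha_T <= 0 or self.alpha_V <= 0:
            raise ValueError("growth rates must be strictly positive")
        if self.K <= 0 or self.T0 <= 0:
            raise ValueError("K and T0 must be strictly positive")
        if self.delta_V < 0 or self.N_max < 0:
            raise ValueError("delta_V and N_max must be non-negative")
        if self.t_norm1 > self.t_norm2:
            raise ValueError("t_norm1 must not exceed t_norm2")
        if abs(self.beta + self.gamma - 1.0) > 1e-12:
            raise ValueError("beta + gamma must equal 1")

    @property
    def V0(self) -> float:
        """Initial carrying capacity, V0 = K * T0 (mm^3)."""
        return self.K * self.T0


@dataclass
class ChemoParams:
    """Chemotherapy delivery/kill constants for the combination model.

    ``alpha_C_tilde`` (mg ml^-1 mm^-3) scales drug delivery, ``k`` (day^-1)
    is the intra-day decay rate after each daily dose, ``delta_T``
    (mg^-1 ml day^-1) the kill coefficient, ``lambda_`` (day^-1) the rate at
    which resistance erodes drug efficacy, and (t_C_on, t_C_off) the dosing
    window in days.
    """

    alpha_C_tilde: float = 1.0
    k: float = 0.9
    delta_T: float = 0.12
    lambda_: float = 0.08
    t_C_on: float = 42.0
    t_C_off: float = 49.0

    def __post_init__(self) -> None:
        if self.t_C_on >= self.t_C_off:
            raise ValueError("t_C_on must be earlier than t_C_off")
        for name in ("alpha_C_tilde", "k", "delta_T", "lambda_"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class Trajectory:
    """Simulated state trajectories on a common time grid."""

    times: np.ndarray
    T: np.ndarray
    V: np.ndarray
    N: np.ndarray
    C: Optional[np.ndarray] = None

    def to_frame(self, id: str | int = 0) -> pd.DataFrame:
        """Tidy representation with columns id, time, T, V, C, N."""
        return pd.DataFrame(
            {
                "id": id,
                "time": self.times,
                "T": self.T,
                "V": self.V,
                "C": np.zeros_like(self.times) if self.C is None else self.C,
                "N": self.N,
            }
        )

    def to_csv(self, path, id: str | int = 0) -> None:
        self.to_frame(id).to_csv(path, index=False)


def normalization_factor(t: float, p: StructuralParams) -> float:
    """Carrying-capacity multiplier N(t).

    Equals ``N_max`` strictly inside the window (t_norm1, t_norm2) and 1
    outside; the boundaries themselves belong to the outer branch.
    """
    if p.t_norm1 < t < p.t_norm2:
        return p.N_max
    return 1.0


def _check_state(T: float, V: float) -> None:
    if T <= 0 or V <= 0:
        raise ValueError(f"non-positive state (T={T}, V={V}) outside model domain")


def rhs_untreated(state, p: StructuralParams):
    """Derivatives (dT/dt, dV/dt) for the untreated model."""
    T, V = state
    _check_state(T, V)
    dT = p.alpha_T * T * (1.0 - T / V)
    dV = p.alpha_V * T**p.beta * V**p.gamma
    return dT, dV


def rhs_treated(t: float, state, p: StructuralParams):
    """Derivatives under antiangiogenic therapy: vessel kill + window."""
    T, V = state
    _check_state(T, V)
    N = normalization_factor(t, p)
    dT = p.alpha_T * T * (1.0 - T / (N * V))
    dV = p.alpha_V * T**p.beta * V**p.gamma - p.delta_V * V
    return dT, dV


#: volumes enter the drug-delivery term in milliliters (1 mm^3 = 1e-3 ml);
#: with the delivery coefficient of order 1 mg ml^-1 mm^-3 this keeps the
#: intratumoral concentration at a physically sensible fraction of a mg/ml
ML_PER_MM3 = 1e-3


def chemo_concentration(t: float, V: float, N: float, cp: ChemoParams) -> float:
    """Algebraic intratumoral drug concentration C(t) (mg ml^-1).

    Zero outside the dosing window; inside it, delivery proportional to the
    effective capacity N*V (V in milliliters) with exponential intra-day
    decay after each daily dose (period 1 day).
    """
    if V <= 0:
        raise ValueError("V must be positive")
    if not (cp.t_C_on < t < cp.t_C_off):
        return 0.0
    return cp.alpha_C_tilde * N * V * ML_PER_MM3 * np.exp(-cp.k * np.mod(t, 1.0))


def rhs_combo(t: float, state, p: StructuralParams, cp: ChemoParams):
    """Derivatives for combined antiangiogenic + chemotherapy.

    The resistance factor exp(-lambda*(t - t_C_on)) erodes the kill term
    with time under drug exposure (the clock starts at chemotherapy onset).
    """
    T, V = state
    _check_state(T, V)
    N = normalization_factor(t, p)
    dT = p.alpha_T * T * (1.0 - T / (N * V))
    dV = p.alpha_V * T**p.beta * V**p.gamma - p.delta_V * V
    C = chemo_concentration(t, V, N, cp)
    if C > 0.0:
        dT -= cp.delta_T * C * T * np.exp(-cp.lambda_ * (t - cp.t_C_on))
    return dT, dV


def _breakpoints(p: StructuralParams, cp: Optional[ChemoParams], model: str,
                 t0: float, t_end: float) -> np.ndarray:
    pts = {t0, t_end}
    if model in ("treated", "combo"):
        pts.update((p.t_norm1, p.t_norm2))
    if model == "combo" and cp is not None:
        pts.update((cp.t_C_on, cp.t_C_off))
        d = np.ceil(cp.t_C_on)
        if d == cp.t_C_on:
            d += 1
        while d <= min(cp.t_C_off, t_end):
            pts.add(float(d))
            d += 1
    return np.array(sorted(t for t in pts if t0 <= t <= t_end))


def _segment_rhs(p: StructuralParams, cp: Optional[ChemoParams], model: str,
                 a: float, b: float):
    """RHS with piecewise branches frozen to their value inside (a, b).

    Freezing N(t) and the dosing switch at the segment midpoint keeps every
    adaptive step smooth; segment edges are exactly the discontinuity times.
    """
    tmid = 0.5 * (a + b)
    N = normalization_factor(tmid, p) if model != "untreated" else 1.0
    dV_rate = 0.0 if model == "untreated" else p.delta_V
    chemo_on = model == "combo" and cp is not None and cp.t_C_on < tmid < cp.t_C_off
    day0 = np.floor(a + 1e-9)

    def rhs(t, y):
        T, V = y
        Ts = max(T, STATE_FLOOR)
        Vs = max(V, STATE_FLOOR)
        dT = p.alpha_T * T * (1.0 - T / (N * Vs))
        dV = p.alpha_V * Ts**p.beta * Vs**p.gamma - dV_rate * V
        if chemo_on:
            C = cp.alpha_C_tilde * N * Vs * ML_PER_MM3 * np.exp(-cp.k * (t - day0))
            dT -= cp.delta_T * C * T * np.exp(-cp.lambda_ * (t - cp.t_C_on))
        return [dT, dV]

    return rhs


def simulate_individual(
    p: StructuralParams,
    times: np.ndarray,
    cp: Optional[ChemoParams] = None,
    model: str = "untreated",
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> Trajectory:
    """Integrate one individual's structural model over ``times``.

    The initial condition is (T0, K*T0) at ``times[0]``.  Integration uses an
    adaptive stiff-capable solver (LSODA) restarted at every right-hand-side
    discontinuity — window boundaries, chemotherapy switches, and each
    integer day inside the dosing window — so no adaptive step straddles a
    jump.

    Raises
    ------
    RuntimeError
        If the solver fails; the message includes the offending parameters.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing vector")
    if model not in ("untreated", "treated", "combo"):
        raise ValueError(f"unknown model {model!r}")
    if model == "combo" and cp is None:
        raise ValueError("combo model requires ChemoParams")

    t0, t_end = float(times[0]), float(times[-1])
    bpts = _breakpoints(p, cp, model, t0, t_end)

    y = np.array([p.T0, p.V0])
    T_out = np.empty_like(times)
    V_out = np.empty_like(times)
    filled = np.zeros(len(times), dtype=bool)
    T_out[0], V_out[0] = y
    filled[0] = True

    for a, b in zip(bpts[:-1], bpts[1:]):
        rhs = _segment_rhs(p, cp, model, a, b)
        interior = (~filled) & (times > a + 1e-12) & (times < b - 1e-12)
        t_eval = np.append(times[interior], b)
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=rtol, atol=atol,
                        t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed on [{a}, {b}] with params {p}: {sol.message}"
            )
        T_out[interior] = sol.y[0][:-1]
        V_out[interior] = sol.y[1][:-1]
        filled[interior] = True
        y = sol.y[:, -1]
        at_end = (~filled) & np.isclose(times, b, rtol=0, atol=1e-9)
        T_out[at_end] = y[0]
        V_out[at_end] = y[1]
        filled[at_end] = True

    N_out = np.array([normalization_factor(t, p) if model != "untreated" else 1.0 for t in times])
    C_out = None
    if model == "combo":
        C_out = np.array(
            [chemo_concentration(t, v, normalization_factor(t, p), cp) for t, v in zip(times, V_out)]
        )
    # the kill term is proportional to T, so the exact solution stays
    # positive; tiny numerical undershoot near zero is clamped to the floor,
    # anything larger is a genuine failure
    if np.any(T_out < -1e-6) or np.any(V_out < -1e-6):
        raise RuntimeError(f"trajectory left the positive domain for params {p}")
    T_out = np.maximum(T_out, STATE_FLOOR)
    V_out = np.maximum(V_out, STATE_FLOOR)
    return Trajectory(times=times, T=T_out, V=V_out, N=N_out, C=C_out)
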