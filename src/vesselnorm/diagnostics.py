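"""Model diagnostics: CWRES, visual predictive checks, observed-vs-predicted.

These reproduce the standard pharmacometric goodness-of-fit surfaces for the
vascular tumor growth model.  Conditional weighted residuals (CWRES) are
computed by first-order conditional (FOCE-style) linearization of the model
around each animal's empirical Bayes estimate; when the model is correct
they are approximately standard normal, and structured departures — e.g. a
positive arm-mean at day 52 with negative arm-means at days 59/63 when a
monotonic vessel-kill model is fitted to data with a transient normalization
window — flag structural misfit.  The visual predictive check simulates
replicate trials from the fitted population law and compares observed
quantiles to their simulation bands.  All computations return tidy frames;
plotting is layered separately in :func:`plot_vpc` and friends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .saem import FitResult
from .trial import LongDataset, TrialDesign, simulate_trial

__all__ = ["VpcResult", "cwres", "arm_mean_cwres", "vpc", "obs_vs_pred", "plot_vpc"]


@dataclass
class VpcResult:
    """Observed quantiles vs simulation-based prediction bands, per arm."""

    arm: str
    bin_times: np.ndarray
    observed_quantiles: pd.DataFrame   # columns q10, q50, q90 indexed by time
    predicted_bands: pd.DataFrame      # columns q{10,50,90}_{lo,mid,hi}
    outliers: List[Tuple[float, str]]  # (time, quantile label)

    @property
    def n_outliers(self) -> int:
        return len(self.outliers)


def _foce_pieces(fit: FitResult, i: int, h: float = 1e-4):
    """Predictions, Jacobian wrt eta, and covariance at one animal's EBE."""
    pr = fit._problem
    eta = fit._eta_hat[i]
    omega_mat = pr.omega_matrix(fit._omega)
    active = pr.active_matrix(fit._omega)
    idx = np.where(active[i])[0]
    mu_mat = pr.mu_matrix(fit._mu)
    z = mu_mat[i] + eta
    f = pr.predict_animal(i, z)
    F = np.zeros((len(f), len(idx)))
    for col, j in enumerate(idx):
        zp = z.copy(); zp[j] += h
        zm = z.copy(); zm[j] -= h
        F[:, col] = (pr.predict_animal(i, zp) - pr.predict_animal(i, zm)) / (2 * h)
    Om = np.diag(omega_mat[i, idx] ** 2)
    if fit.spec.error_model == "proportional":
        R = np.diag((fit.b_hat * f) ** 2)
    else:
        R = fit.b_hat**2 * np.eye(len(f))
    cov = F @ Om @ F.T + R
    mean = f - F @ eta[idx]
    return f, mean, cov


def cwres(fit: FitResult, data: Optional[LongDataset] = None) -> pd.DataFrame:
    """Conditional weighted residuals, one row per observation.

    FOCE-style: for animal i the marginal law of y_i is approximated by
    linearizing f around the EBE eta_i, giving mean f(eta_i) - F eta_i and
    covariance F Omega F' + R; CWRES are the Cholesky-whitened residuals.
    Returns columns ID, ARM, TIME, DV, PRED, CWRES.  A singular covariance
    for an animal falls back to individual weighted residuals
    (y - f) / g(f), flagged in the ``flagged`` column.
    """
    pr = fit._problem
    rows = []
    for i, animal in enumerate(pr.animals):
        y = pr.y_flat[pr.offsets[i]:pr.offsets[i + 1]]
        t = pr.t_flat[pr.offsets[i]:pr.offsets[i + 1]]
        f, mean, cov = _foce_pieces(fit, i)
        flagged = False
        try:
            L = np.linalg.cholesky(cov)
            w = np.linalg.solve(L, y - mean)
        except np.linalg.LinAlgError:
            flagged = True
            g = fit.b_hat * f if fit.spec.error_model == "proportional" else fit.b_hat
            w = (y - f) / g
        for k in range(len(y)):
            rows.append(dict(ID=animal, ARM=pr.arm_of[animal], TIME=t[k],
                             DV=y[k], PRED=f[k], CWRES=w[k], flagged=flagged))
    return pd.DataFrame(rows)


def arm_mean_cwres(table: pd.DataFrame) -> pd.DataFrame:
    """Mean CWRES per (ARM, TIME) — the curves drawn in residual panels."""
    return (
        table.groupby(["ARM", "TIME"], as_index=False)["CWRES"].mean()
        .rename(columns={"CWRES": "mean_cwres"})
    )


def vpc(
    fit: FitResult,
    data: LongDataset,
    n_rep: int = 500,
    seed: int = 0,
    design: Optional[TrialDesign] = None,
) -> List[VpcResult]:
    """Visual predictive check, one result per arm.

    Simulates ``n_rep`` replicate trials from the fitted population law
    (including the fitted T0 law), bins by nominal measurement day, and
    compares the observed 10/50/90% quantiles with the central 90% interval
    of each quantile across replicates.  Observed quantile points outside
    their band are flagged as outliers.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    pop = fit.population()
    frame = data.frame
    arms = list(dict.fromkeys(frame["ARM"]))
    times = np.array(sorted(frame["TIME"].unique()))
    if design is None:
        counts = frame.groupby("ARM")["ID"].nunique()
        t0_law = _fitted_t0_law(fit)
        design = TrialDesign(
            arms=tuple((a, int(counts[a])) for a in arms),
            dose_days=(float(times[0]),),
            measurement_days=tuple(times),
            T0_mean=t0_law[0],
            T0_cv=t0_law[1],
        )
    qlabels = ("q10", "q50", "q90")
    qs = (0.1, 0.5, 0.9)

    sim_q = {a: np.empty((n_rep, len(times), 3)) for a in arms}
    ss = np.random.SeedSequence(int(seed) % 2**31)
    for r, child in enumerate(ss.spawn(n_rep)):
        sim, _ = simulate_trial(pop, design, child)
        sf = sim.frame
        for a in arms:
            sub = sf[sf["ARM"] == a].pivot(index="ID", columns="TIME", values="DV")
            sub = sub.reindex(columns=times)
            sim_q[a][r] = np.nanquantile(sub.to_numpy(), qs, axis=0).T

    results = []
    for a in arms:
        obs = frame[frame["ARM"] == a].pivot(index="ID", columns="TIME", values="DV")
        obs = obs.reindex(columns=times)
        oq = np.nanquantile(obs.to_numpy(), qs, axis=0).T  # (time, 3)
        bands = {}
        outliers = []
        for qi, ql in enumerate(qlabels):
            lo = np.quantile(sim_q[a][:, :, qi], 0.05, axis=0)
            hi = np.quantile(sim_q[a][:, :, qi], 0.95, axis=0)
            mid = np.quantile(sim_q[a][:, :, qi], 0.5, axis=0)
            bands[f"{ql}_lo"] = lo
            bands[f"{ql}_mid"] = mid
            bands[f"{ql}_hi"] = hi
            for k, tt in enumerate(times):
                if not (lo[k] <= oq[k, qi] <= hi[k]):
                    outliers.append((float(tt), ql))
        results.append(VpcResult(
            arm=a,
            bin_times=times,
            observed_quantiles=pd.DataFrame(
                {ql: oq[:, qi] for qi, ql in enumerate(qlabels)}, index=times,
            ),
            predicted_bands=pd.DataFrame(bands, index=times),
            outliers=outliers,
        ))
    return results


def _fitted_t0_law(fit: FitResult) -> Tuple[float, float]:
    """(mean, CV) of the fitted log-normal T0 law."""
    med = fit.theta_hat.get("T0")
    w = fit.omega_hat.get("T0", 0.0)
    if med is None:
        return 70.0, 0.0
    mean = med * np.exp(0.5 * w**2)
    cv = float(np.sqrt(np.expm1(w**2)))
    return float(mean), cv


def obs_vs_pred(fit: FitResult, data: Optional[LongDataset] = None) -> Tuple[pd.DataFrame, dict]:
    """Observed vs individual-predicted volumes plus identity-line summary.

    Individual predictions use each animal's EBE parameters.  Returns the
    paired table (ID, ARM, TIME, DV, IPRED) and summary statistics of the
    regression of observations on predictions (slope through the origin and
    R^2 about the identity line).
    """
    pr = fit._problem
    if data is not None:
        missing = set(data.animals) - set(pr.animals)
        if missing:
            raise KeyError(f"animals missing from fit: {sorted(missing)}")
    rows = []
    mu_mat = pr.mu_matrix(fit._mu)
    for i, animal in enumerate(pr.animals):
        y = pr.y_flat[pr.offsets[i]:pr.offsets[i + 1]]
        t = pr.t_flat[pr.offsets[i]:pr.offsets[i + 1]]
        f = pr.predict_animal(i, mu_mat[i] + fit._eta_hat[i])
        for k in range(len(y)):
            rows.append(dict(ID=animal, ARM=pr.arm_of[animal], TIME=t[k],
                             DV=y[k], IPRED=f[k]))
    table = pd.DataFrame(rows)
    x = table["IPRED"].to_numpy()
    y = table["DV"].to_numpy()
    slope = float(np.sum(x * y) / np.sum(x * x))
    ss_res = float(np.sum((y - x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    summary = {"slope": slope, "r2_identity": 1.0 - ss_res / ss_tot,
               "n": len(table)}
    return table, summary


def plot_vpc(results: List[VpcResult], path=None):
    """Render per-arm VPC panels (matplotlib); returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(results), figsize=(4.2 * len(results), 3.6),
                             sharey=True, squeeze=False)
    for ax, res in zip(axes[0], results):
        t = res.bin_times
        bands = res.predicted_bands
        for ql, color in (("q10", "tab:blue"), ("q50", "tab:red"), ("q90", "tab:blue")):
            ax.fill_between(t, bands[f"{ql}_lo"], bands[f"{ql}_hi"],
                            alpha=0.25, color=color, lw=0)
            ax.plot(t, res.observed_quantiles[ql], color="green", lw=1.5)
        for tt, ql in res.outliers:
            ax.plot(tt, res.observed_quantiles.loc[tt, ql], "o", mfc="none",
                    mec="red", ms=9)
        ax.set_title(res.arm)
        ax.set_xlabel("day after inoculation")
    axes[0][0].set_ylabel("tumor volume (mm$^3$)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
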