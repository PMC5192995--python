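"""Dataset and report I/O plus run configuration.

The long-format dialect follows pharmacometric convention (columns ID, TIME,
DV, ARM, optional MDV), so Monolix/NONMEM-style exports load unchanged.
Times are days since tumor-cell inoculation (treatment start = day 38 in the
default design).  Fit reports are emitted both as a parameter table shaped
like the published population-parameter tables (estimate, RSE%, IIV, RSE%,
shrinkage%, with fixed entries annotated ``FIX``) and as JSON for machines.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .saem import FitResult, ModelSpec, SaemSettings
from .trial import LongDataset, TrialDesign

__all__ = [
    "read_long_dataset",
    "write_long_dataset",
    "write_fit_report",
    "fit_report_frame",
    "RunConfig",
]

_PARAM_META = {
    "alpha_T": ("day^-1", "Tumor growth rate"),
    "alpha_V": ("day^-1", "Vessel growth rate"),
    "K": ("", "Initial ratio of V/T"),
    "T0": ("mm^3", "Initial tumor volume"),
    "t_norm1": ("days", "Start time of normalization window"),
    "t_norm2": ("days", "End time of normalization window"),
    "N_max": ("", "Maximum normalization constant"),
    "delta_V": ("day^-1", "Vessel kill rate"),
}


def read_long_dataset(
    path: Union[str, Path],
    valid_arms: Optional[Sequence[str]] = None,
) -> LongDataset:
    """Read and validate a long-format tumor-size CSV.

    Requires columns ID, TIME, DV, ARM (MDV optional; rows with MDV != 0 are
    dropped).  Rejects non-positive volumes and duplicate (ID, TIME) records
    with the offending row number in the message; if ``valid_arms`` is
    given, unknown arm labels are rejected with the allowed list.
    """
    frame = pd.read_csv(path)
    required = ["ID", "TIME", "DV", "ARM"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if valid_arms is not None:
        unknown = sorted(set(frame["ARM"]) - set(valid_arms))
        if unknown:
            raise ValueError(
                f"{path}: unknown ARM label(s) {unknown}; valid arms: "
                f"{sorted(valid_arms)}"
            )
    if "MDV" in frame.columns:
        frame = frame[frame["MDV"] == 0].copy()
    else:
        frame["MDV"] = 0
    bad = frame.index[frame["DV"] <= 0]
    if len(bad):
        raise ValueError(f"{path}: non-positive DV at row {bad[0] + 2} (column DV)")
    dup = frame.duplicated(subset=["ID", "TIME"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (ID, TIME) record at row {frame.index[dup][0] + 2}"
        )
    return LongDataset(frame[required + ["MDV"]])


def write_long_dataset(data: LongDataset, path: Union[str, Path]) -> None:
    # 17 significant digits keep read -> write -> read an exact identity
    data.frame.to_csv(path, index=False, float_format="%.17g")


def _row_meta(name: str):
    if name.startswith("delta_V"):
        units, desc = _PARAM_META["delta_V"]
        arm = name[len("delta_V_"):] if len(name) > len("delta_V") else ""
        if arm:
            desc = f"{desc} ({arm})"
        return units, desc
    for base, meta in _PARAM_META.items():
        if name == base or name.startswith(base + "_"):
            units, desc = meta
            suffix = name[len(base) + 1:]
            return units, f"{desc} ({suffix})" if suffix else desc
    return "", name


def fit_report_frame(fit: FitResult) -> pd.DataFrame:
    """Population-parameter table: estimate, RSE%, IIV, RSE%, shrinkage%."""
    if not fit.theta_hat:
        raise ValueError("empty fit: no estimates to report")
    rows = []
    for name, est in fit.theta_hat.items():
        units, desc = _row_meta(name)
        fixed_theta = name in fit.fixed
        omega = fit.omega_hat.get(name)
        omega_fixed = f"omega_{name}" in fit.fixed
        rows.append(dict(
            parameter=name,
            units=units,
            description=desc,
            estimate=f"{est:.4g} FIX" if fixed_theta else round(est, 4),
            rse_pct=None if fixed_theta else _round(fit.rse.get(name)),
            iiv_sd=(
                f"{fit.fixed[f'omega_{name}']:.3g} FIX" if omega_fixed
                else (round(omega, 4) if omega is not None else None)
            ),
            iiv_rse_pct=None if omega_fixed else _round(fit.rse.get(f"omega_{name}")),
            shrinkage_pct=_round(100 * fit.shrinkage[name]) if name in fit.shrinkage else None,
        ))
    rows.append(dict(
        parameter="b", units="%",
        description="Proportional error parameter"
        if fit.spec.error_model == "proportional" else "Constant error parameter (mm^3)",
        estimate=round(100 * fit.b_hat, 2) if fit.spec.error_model == "proportional"
        else round(fit.b_hat, 3),
        rse_pct=_round(fit.rse.get("b")),
        iiv_sd=None, iiv_rse_pct=None, shrinkage_pct=None,
    ))
    return pd.DataFrame(rows)


def _round(x, nd=1):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return None
    return round(float(x), nd)


def write_fit_report(fit: FitResult, path_prefix: Union[str, Path]) -> dict:
    """Write ``<prefix>_parameters.csv``, ``<prefix>.json`` and the trace.

    Returns the JSON payload (estimates, precision, likelihood, BIC).
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    table = fit_report_frame(fit)
    table.to_csv(f"{prefix}_parameters.csv", index=False)
    payload = {
        "theta": fit.theta_hat,
        "omega": fit.omega_hat,
        "b": fit.b_hat,
        "rse_pct": {k: (v if np.isfinite(v) else None) for k, v in fit.rse.items()},
        "shrinkage": fit.shrinkage,
        "fixed": fit.fixed,
        "loglik": None if np.isnan(fit.loglik) else fit.loglik,
        "loglik_se": None if np.isnan(fit.loglik_se) else fit.loglik_se,
        "bic": None if np.isnan(fit.bic) else fit.bic,
        "d": fit.d,
        "n_obs": fit.n_obs,
        "structural": fit.spec.structural,
        "error_model": fit.spec.error_model,
        "sharing": fit.spec.sharing,
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    fit.convergence_trace.to_csv(f"{prefix}_trace.csv", index=False)
    return payload


@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce a run, round-trippable through YAML."""

    design: TrialDesign = dataclasses.field(default_factory=TrialDesign)
    spec: ModelSpec = dataclasses.field(default_factory=ModelSpec)
    settings: SaemSettings = dataclasses.field(default_factory=SaemSettings)
    seed: int = 1
    output_dir: str = "results"

    def to_yaml(self, path: Union[str, Path]) -> None:
        payload = {
            "design": dataclasses.asdict(self.design),
            "spec": dataclasses.asdict(self.spec),
            "settings": dataclasses.asdict(self.settings),
            "seed": self.seed,
            "output_dir": self.output_dir,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(payload), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        design = payload.get("design", {})
        design["arms"] = tuple(tuple(a) for a in design.get("arms", ()))
        for key in ("dose_days", "measurement_days"):
            if key in design:
                design[key] = tuple(design[key])
        spec = payload.get("spec", {})
        if "control_arms" in spec:
            spec["control_arms"] = tuple(spec["control_arms"])
        return cls(
            design=TrialDesign(**design),
            spec=ModelSpec(**spec),
            settings=SaemSettings(**payload.get("settings", {})),
            seed=int(payload.get("seed", 1)),
            output_dir=str(payload.get("output_dir", "results")),
        )


def _plain(obj):
    """YAML-safe containers: tuples -> lists, numpy scalars -> python."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj
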