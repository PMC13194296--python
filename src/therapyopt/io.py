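"""CSV/YAML/JSON serialization of ensembles, schedules, and model specs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    DEFAULT_R_S,
    EnsembleMeasure,
    GeneralModelSpec,
    InvalidParameterError,
    ThetaTwoPop,
)
from .simulate import ControlGrid, TrajectoryBundle, TTPSummary

__all__ = [
    "write_ensemble_csv",
    "read_ensemble_csv",
    "write_control_csv",
    "read_control_csv",
    "write_trajectory_csv",
    "write_ttp_csv",
    "write_general_spec",
    "read_general_spec",
]

ENSEMBLE_COLUMNS = ["d_hat_D", "d_hat_T", "r_hat_R", "f_hat_0", "n0", "weight"]


def write_ensemble_csv(ensemble: EnsembleMeasure, path) -> None:
    """One support point per row: ``d_hat_D,d_hat_T,r_hat_R,f_hat_0,n0,weight``."""
    rows = [th.astuple() + (w,) for th, w in zip(ensemble.support, ensemble.weights)]
    # %.17g keeps the round-trip bit-exact
    pd.DataFrame(rows, columns=ENSEMBLE_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_ensemble_csv(path) -> EnsembleMeasure:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ENSEMBLE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"ensemble CSV is missing columns {missing}")
    support = [
        ThetaTwoPop(r.d_hat_D, r.d_hat_T, r.r_hat_R, r.f_hat_0, r.n0)
        for r in df.itertuples()
    ]
    return EnsembleMeasure(support, df["weight"].to_numpy())


def write_control_csv(control: ControlGrid, path, r_s: float = DEFAULT_R_S) -> None:
    """Schedule as ``day,u`` rows (one per Euler step, left endpoint)."""
    days = control.times[:-1] / r_s
    pd.DataFrame({"day": days, "u": control.values}).to_csv(path, index=False)


def read_control_csv(path, r_s: float = DEFAULT_R_S) -> ControlGrid:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("day", "u"):
        if col not in df.columns:
            raise InvalidParameterError(f"control CSV is missing column {col!r}")
    days = df["day"].to_numpy(dtype=float)
    if len(days) < 2:
        raise InvalidParameterError("control CSV must hold at least two steps")
    step = (days[1] - days[0]) * r_s
    times = np.append(days * r_s, days[-1] * r_s + step)
    return ControlGrid(times - times[0], df["u"].to_numpy(dtype=float))


def write_trajectory_csv(
    traj: TrajectoryBundle, path, member: int = 0, r_s: float = DEFAULT_R_S
) -> None:
    """Single-member path as ``tau,day,s,r,n,u`` (u blank at the final node)."""
    s = traj.s[:, member]
    r = traj.r[:, member]
    u = np.full(len(s), np.nan)
    if traj.controls is not None:
        ctrl = traj.controls if traj.controls.ndim == 1 else traj.controls[:, member]
        u[:-1] = ctrl
    pd.DataFrame(
        {
            "tau": traj.times,
            "day": traj.times / r_s,
            "s": s,
            "r": r,
            "n": s + r,
            "u": u,
        }
    ).to_csv(path, index=False)


def write_ttp_csv(summary: TTPSummary, path) -> None:
    """Per-member progression times with parameters and censoring flags."""
    rows = []
    for i, th in enumerate(summary.thetas):
        rows.append(
            {
                "d_hat_D": th.d_hat_D,
                "d_hat_T": th.d_hat_T,
                "r_hat_R": th.r_hat_R,
                "f_hat_0": th.f_hat_0,
                "ttp_days": int(np.floor(summary.ttp_days[i])),
                "ttp_prime_days": int(np.floor(summary.ttp_prime_days[i])),
                "censored": bool(summary.ttp_censored[i]),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# General model spec
# --------------------------------------------------------------------------

def _spec_to_dict(spec: GeneralModelSpec) -> dict:
    return {
        "n_species": spec.n_species,
        "r": spec.r.tolist(),
        "K": spec.K,
        "d_I": spec.d_I.tolist(),
        "d_T": spec.d_T.tolist(),
        "A": spec.A.tolist(),
        "A_I": spec.A_I.tolist(),
        "f": spec.f.tolist(),
        "N0": spec.N0,
        "D_max": spec.D_max,
        "K_min": spec.K_min,
        "K_max": spec.K_max,
    }


def write_general_spec(spec: GeneralModelSpec, path) -> None:
    """YAML or JSON by file extension; matrices row-major."""
    path = Path(path)
    data = _spec_to_dict(spec)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        raise InvalidParameterError(f"unsupported spec format {path.suffix!r}")


def read_general_spec(path) -> GeneralModelSpec:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
    elif path.suffix == ".json":
        data = json.loads(path.read_text())
    else:
        raise InvalidParameterError(f"unsupported spec format {path.suffix!r}")
    return GeneralModelSpec(
        n_species=int(data["n_species"]),
        r=np.asarray(data["r"], dtype=float),
        K=float(data["K"]),
        d_I=np.asarray(data["d_I"], dtype=float),
        d_T=np.asarray(data["d_T"], dtype=float),
        A=np.asarray(data["A"], dtype=float),
        A_I=np.asarray(data["A_I"], dtype=float),
        f=np.asarray(data["f"], dtype=float),
        N0=float(data["N0"]),
        D_max=float(data.get("D_max", 1.0)),
        K_min=data.get("K_min"),
        K_max=data.get("K_max"),
    )
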