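"""Reading and writing trial series, trajectories, priors and fit results.

Trial series are CSV/TSV files with a header; the only required column
is ``u``.  Optional columns: ``trial`` (ignored beyond ordering), ``y``
(binary responses, blank = missing), ``t`` (positive inter-trial
intervals, default 1), ``rA``/``rB`` (bandit rewards).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hgfilter.continuous import Trajectory, TrialSeries
from hgfilter.exceptions import InputFormatError
from hgfilter.inversion import FitResult, Prior

__all__ = [
    "read_trial_series",
    "write_trial_series",
    "write_trajectory",
    "read_trajectory",
    "priors_from_dict",
    "priors_to_dict",
    "read_priors",
    "fit_result_to_dict",
    "write_fit_result",
]


def _dialect_sep(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return "," if dialect == "csv" else "\t"
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_trial_series(path: str | Path, dialect: str | None = None) -> TrialSeries:
    """Parse a trial-series file, validating each optional column.

    Errors name the offending data line (1-based, counting the header as
    line 1).
    """
    df = pd.read_csv(path, sep=_dialect_sep(path, dialect),
                     float_precision="round_trip")
    if "u" not in df.columns:
        raise InputFormatError(f"{path}: required column 'u' is missing")

    def line_of(mask: np.ndarray) -> int:
        return int(np.nonzero(mask)[0][0]) + 2  # +1 header, +1 one-based

    y = None
    if "y" in df.columns:
        y = df["y"].to_numpy(dtype=float)
        bad = ~np.isnan(y) & ~np.isin(y, (0.0, 1.0))
        if bad.any():
            raise InputFormatError(
                f"{path}: non-binary response y = {y[bad][0]!r} on line {line_of(bad)}")
    t = None
    if "t" in df.columns:
        t = df["t"].to_numpy(dtype=float)
        t = np.where(np.isnan(t), 1.0, t)
        bad = t <= 0
        if bad.any():
            raise InputFormatError(
                f"{path}: non-positive interval t = {t[bad][0]!r} on line {line_of(bad)}")
    kwargs = {}
    for col, attr in (("rA", "r_a"), ("rB", "r_b")):
        if col in df.columns:
            kwargs[attr] = df[col].to_numpy(dtype=float)
    return TrialSeries(u=df["u"].to_numpy(dtype=float), y=y, t=t, **kwargs)


def write_trial_series(series: TrialSeries, path: str | Path,
                       dialect: str | None = None) -> None:
    data = {"trial": np.arange(1, series.K + 1), "u": series.u}
    if series.y is not None:
        data["y"] = series.y
    data["t"] = series.t
    if series.r_a is not None:
        data["rA"] = series.r_a
    if series.r_b is not None:
        data["rB"] = series.r_b
    pd.DataFrame(data).to_csv(path, sep=_dialect_sep(path, dialect), index=False,
                              float_format="%.17g")


def _trajectory_frame(trajectory: Trajectory) -> pd.DataFrame:
    cols = {"trial": np.arange(1, trajectory.K + 1)}
    for i in range(trajectory.n_levels):
        lev = i + 1
        cols[f"muhat_{lev}"] = trajectory.mu_hat[:, i]
        cols[f"pihat_{lev}"] = trajectory.pi_hat[:, i]
        cols[f"mu_{lev}"] = trajectory.mu[:, i]
        cols[f"pi_{lev}"] = trajectory.pi[:, i]
        cols[f"v_{lev}"] = trajectory.v[:, i]
        cols[f"delta_{lev}"] = trajectory.delta[:, i]
        if trajectory.psi is not None:
            cols[f"psi_{lev}"] = trajectory.psi[:, i]
    cols["delta_u"] = trajectory.delta_u
    return pd.DataFrame(cols)


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Per-trial, per-level CSV with a deterministic column order."""
    _trajectory_frame(trajectory).to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    levels = sorted(int(c.split("_")[1]) for c in df.columns if c.startswith("mu_"))
    n = len(levels)

    def block(prefix):
        return np.column_stack([df[f"{prefix}_{lev}"].to_numpy() for lev in levels])

    psi = block("psi") if f"psi_{levels[0]}" in df.columns else None
    return Trajectory(mu_hat=block("muhat"), pi_hat=block("pihat"), v=block("v"),
                      mu=block("mu"), pi=block("pi"), delta=block("delta"),
                      delta_u=df["delta_u"].to_numpy(), psi=psi)


def priors_from_dict(spec: dict) -> dict[str, Prior]:
    """Build a prior set from a plain mapping (e.g. parsed YAML/JSON).

    Each entry is ``name: {space, mean, variance[, bound]}``.
    """
    priors = {}
    for name, entry in spec.items():
        unknown = set(entry) - {"space", "mean", "variance", "bound"}
        if unknown:
            raise InputFormatError(f"prior {name!r}: unknown keys {sorted(unknown)}")
        priors[name] = Prior(space=entry["space"], mean=float(entry["mean"]),
                             variance=float(entry["variance"]),
                             bound=entry.get("bound"))
    return priors


def priors_to_dict(priors: dict[str, Prior]) -> dict:
    out = {}
    for name, p in priors.items():
        entry = {"space": p.space, "mean": p.mean, "variance": p.variance}
        if p.bound is not None:
            entry["bound"] = p.bound
        out[name] = entry
    return out


def read_priors(path: str | Path) -> dict[str, Prior]:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict):
        raise InputFormatError(f"{path}: expected a mapping of priors")
    return priors_from_dict(spec)


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "xi_map": fit.xi_map,
        "xi_map_est": fit.xi_map_est,
        "objective": fit.objective,
        "log_evidence": fit.log_evidence,
        "free_names": fit.free_names,
        "n_function_evals": fit.n_function_evals,
        "converged": fit.converged,
    }


def write_fit_result(fit: FitResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_result_to_dict(fit), fh, indent=2)
        fh.write("\n")
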