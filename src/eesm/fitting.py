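"""Material-parameter estimation from cyclic uniaxial stress-stretch data.

The loading branches of a multi-cycle test are described by the virgin
stress law above the previous cycle's maximum stretch and by the softened
(Mullins) law below it; unloading branches by the softened law at the
current cycle's reversal stretch.  Parameters are estimated by bounded
least squares on engineering stress, pooled over all branches, with a
seeded Latin-hypercube multi-start to cope with the non-convex landscape.

Identifiability: in uniaxial data the volume fraction ``f`` enters only
through the products ``(1-f)*mu``, ``f*A1`` and ``f*A2``, and ``C`` only
through ``mu*C``, so individual values of mu, f, A1, A2, C trade off along
flat directions of the objective.  Fits are therefore validated predictively
(recovered stress curves) and through those identifiable combinations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from eesm.constitutive import (
    DomainError,
    MaterialParams,
    softened_stress_vec,
    virgin_stress_vec,
)

__all__ = [
    "ExperimentCurve",
    "FitResult",
    "FitOptions",
    "predict_curve",
    "predict_stresses",
    "fit_material_params",
    "r_squared",
]

_COLUMNS = ["lam", "stress_kPa", "branch", "cycle"]
_BRANCHES = ("loading", "unloading")


@dataclass
class ExperimentCurve:
    """Labeled loading/unloading stress-stretch samples.

    ``data`` has columns lam, stress_kPa, branch ("loading"/"unloading"),
    cycle (1-based int).  ``metadata`` records provenance (source, seed,
    noise level for synthetic curves).
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"curve data missing columns: {missing}")
        bad = set(self.data["branch"].unique()) - set(_BRANCHES)
        if bad:
            raise ValueError(f"unknown branch labels: {sorted(bad)}")
        if (self.data["lam"] < 1.0 - 1e-9).any():
            raise ValueError("all stretches must be >= 1")
        for (cyc, br), grp in self.data.groupby(["cycle", "branch"], sort=False):
            lam = grp["lam"].to_numpy()
            if br == "loading" and np.any(np.diff(lam) < -1e-12):
                raise ValueError(f"cycle {cyc} loading stretches must be non-decreasing")
            if br == "unloading" and np.any(np.diff(lam) > 1e-12):
                raise ValueError(f"cycle {cyc} unloading stretches must be non-increasing")

    @property
    def cycles(self) -> list[int]:
        return sorted(self.data["cycle"].unique())

    def lam_max_of_cycle(self, cycle: int) -> float:
        return float(self.data.loc[self.data["cycle"] == cycle, "lam"].max())

    def to_csv(self, path: Union[str, Path]) -> None:
        path = Path(path)
        self.data[_COLUMNS].to_csv(path, index=False)
        if self.metadata:
            path.with_suffix(".meta.json").write_text(
                json.dumps(self.metadata, indent=2, default=str) + "\n"
            )

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ExperimentCurve":
        path = Path(path)
        data = pd.read_csv(path)
        meta_path = path.with_suffix(".meta.json")
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(data=data, metadata=metadata)


# ---------------------------------------------------------------------------
# Forward prediction
# ---------------------------------------------------------------------------

def predict_stresses(
    params: MaterialParams,
    lam: np.ndarray,
    branch: Sequence[str],
    cycle: np.ndarray,
    cycle_lam_max: dict,
) -> np.ndarray:
    """Model engineering stress at each (lam, branch, cycle) sample.

    Branch selection follows the standard Mullins idealization: a loading
    sample at or above the previous cycle's maximum follows the virgin law;
    loading below the previous maximum (reloading) and all unloading
    samples follow the softened law at the relevant reversal stretch.
    """
    lam = np.asarray(lam, dtype=float)
    cycle = np.asarray(cycle)
    out = np.empty_like(lam)
    order = sorted(cycle_lam_max)
    prev_max = {c: (cycle_lam_max[order[i - 1]] if i > 0 else 1.0)
                for i, c in enumerate(order)}
    branch = np.asarray(branch)
    for c in order:
        lmax_c, pmax_c = cycle_lam_max[c], prev_max[c]
        in_c = cycle == c
        # unloading: softened branch at this cycle's reversal stretch
        sel = in_c & (branch == "unloading")
        if sel.any():
            out[sel] = softened_stress_vec(lam[sel], lmax_c, params)
        # reloading below the historical maximum: softened at previous max
        sel = in_c & (branch == "loading") & (lam < pmax_c - 1e-12)
        if sel.any():
            out[sel] = softened_stress_vec(lam[sel], pmax_c, params)
        # first loading: virgin law
        sel = in_c & (branch == "loading") & (lam >= pmax_c - 1e-12)
        if sel.any():
            out[sel] = virgin_stress_vec(lam[sel], params)
    return out


def predict_curve(params: MaterialParams, schedule: pd.DataFrame) -> ExperimentCurve:
    """Evaluate the model along a (lam, branch, cycle) schedule.

    ``schedule`` needs columns lam, branch, cycle; reversal stretches are
    taken as each cycle's maximum stretch.  Raises :class:`DomainError` if
    the schedule violates Mullins history (an unloading sample above its
    cycle's maximum cannot occur by construction; a loading sample beyond
    the lock stretch raises from the constitutive layer).
    """
    df = schedule[["lam", "branch", "cycle"]].copy()
    cycle_lam_max = {
        int(c): float(df.loc[df["cycle"] == c, "lam"].max())
        for c in df["cycle"].unique()
    }
    maxes = [cycle_lam_max[c] for c in sorted(cycle_lam_max)]
    if np.any(np.diff(maxes) <= 0):
        raise DomainError("cycle maximum stretches must be strictly increasing")
    df["stress_kPa"] = predict_stresses(
        params, df["lam"].to_numpy(), df["branch"], df["cycle"].to_numpy(),
        cycle_lam_max,
    )
    return ExperimentCurve(
        data=df[_COLUMNS], metadata={"source": "model", **params.to_dict()}
    )


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    SS_tot is taken about the observed mean.  Can be negative for fits
    worse than the mean predictor.  Raises on zero observed variance.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D arrays")
    if observed.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = np.sum((observed - observed.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("observed values have zero variance")
    ss_res = np.sum((observed - predicted) ** 2)
    return float(1.0 - ss_res / ss_tot)


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    """Optimizer settings for :func:`fit_material_params`.

    ``n_starts`` Latin-hypercube starting points are drawn over the
    log-scaled box (linear for f); ``seed`` makes the whole fit
    deterministic.  ``relative_loss`` switches the residuals to relative
    error (each residual divided by max(|obs|, rel_floor)).
    """

    n_starts: int = 20
    seed: int = 42
    relative_loss: bool = False
    rel_floor: float = 0.05  # kPa, guards division near zero stress
    max_nfev: int = 400


_BOUND_LO = np.array([1e-4, 1.01, 0.0, 0.0, 0.0, 0.0, 0.0])
_BOUND_HI = np.array([1e3, 100.0, 100.0, 1e6, 1e6, 1e6, 1.0])
_PARAM_ORDER = ("mu", "N", "b", "A1", "A2", "C", "f")
# sampling floors for log-scaled LHS where the true lower bound is 0
_LHS_LO = np.array([1e-3, 1.01, 1e-2, 1e-2, 1.0, 1e-2, 1e-3])
_LHS_HI = np.array([10.0, 10.0, 50.0, 1e3, 1e5, 1e3, 1.0])


@dataclass
class FitResult:
    """Best fit with convergence diagnostics."""

    params: MaterialParams
    r2_loading: float
    r2_unloading: float
    residuals: np.ndarray
    n_starts: int
    best_objective: float
    n_iterations: int
    objective_per_start: list = field(default_factory=list)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "params": self.params.to_dict(),
            "r2_loading": self.r2_loading,
            "r2_unloading": self.r2_unloading,
            "best_objective": self.best_objective,
            "n_starts": self.n_starts,
            "n_iterations": self.n_iterations,
            "objective_per_start": self.objective_per_start,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _residual_fn(curve: ExperimentCurve, options: FitOptions):
    df = curve.data
    lam = df["lam"].to_numpy()
    obs = df["stress_kPa"].to_numpy()
    branch = df["branch"].to_numpy()
    cycle = df["cycle"].to_numpy()
    cycle_lam_max = {c: curve.lam_max_of_cycle(c) for c in curve.cycles}
    scale = np.maximum(np.abs(obs), options.rel_floor) if options.relative_loss else 1.0
    lam_top = max(cycle_lam_max.values())
    # lock-stretch feasibility: sqrt(I1/3N) < 1 at the largest stretch
    n_floor = (lam_top**2 + 2.0 / lam_top) / 3.0 * (1.0 + 1e-6)

    def residuals(x):
        mu, N, b, A1, A2, C, f = x
        if N <= n_floor:
            return np.full_like(obs, 1e6)
        p = MaterialParams(mu=mu, N=N, b=b, A1=A1, A2=A2, C=C, f=f, n=1.0)
        try:
            pred = predict_stresses(p, lam, branch, cycle, cycle_lam_max)
        except (DomainError, FloatingPointError):
            return np.full_like(obs, 1e6)
        return (pred - obs) / scale

    return residuals, obs, branch, n_floor


def fit_material_params(
    curve: ExperimentCurve, options: FitOptions | None = None
) -> FitResult:
    """Estimate MaterialParams from a cyclic uniaxial curve.

    Bounded least squares (trust-region reflective) over
    (mu, N, b, A1, A2, C, f) with n fixed at 1, multi-started from a seeded
    Latin hypercube over log-scaled bounds.  Deterministic given
    ``options.seed``; sample order does not affect the result.
    """
    options = options or FitOptions()
    df = curve.data
    if not (df["branch"] == "loading").any() or not (df["branch"] == "unloading").any():
        raise ValueError("curve must contain at least one loading and one unloading branch")

    residuals, obs, branch, n_floor = _residual_fn(curve, options)
    lo = _BOUND_LO.copy()
    lo[1] = max(lo[1], n_floor)
    lhs_lo = np.maximum(_LHS_LO, lo)

    sampler = qmc.LatinHypercube(d=7, seed=options.seed)
    unit = sampler.random(options.n_starts)
    # log-scale all but f (index 6), which is sampled linearly on [0, 1]
    log_lo, log_hi = np.log(lhs_lo), np.log(_LHS_HI)
    starts = np.exp(log_lo + unit * (log_hi - log_lo))
    starts[:, 6] = unit[:, 6]

    best = None
    objectives = []
    for x0 in starts:
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, _BOUND_HI),
                method="trf", max_nfev=options.max_nfev,
            )
        except Exception:
            objectives.append(float("inf"))
            continue
        objectives.append(float(res.cost))
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    mu, N, b, A1, A2, C, f = best.x
    params = MaterialParams(mu=mu, N=N, b=b, A1=A1, A2=A2, C=C, f=f, n=1.0)
    raw_res = residuals(best.x)
    load = branch == "loading"
    pred = obs + raw_res * (np.maximum(np.abs(obs), options.rel_floor)
                            if options.relative_loss else 1.0)
    return FitResult(
        params=params,
        r2_loading=r_squared(obs[load], pred[load]),
        r2_unloading=r_squared(obs[~load], pred[~load]),
        residuals=raw_res,
        n_starts=options.n_starts,
        best_objective=float(best.cost),
        n_iterations=int(best.nfev),
        objective_per_start=objectives,
    )
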