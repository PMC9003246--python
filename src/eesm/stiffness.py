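"""Equivalent-energy stiffness tables: the hybrid SEDF -> spring step.

A one-dimensional spring of stretch ``lam`` stores energy density
``W_s = ks * lam * (lam - 1) / (2 * nu_ij)`` where ``nu_ij`` is the
transversal-area geometric parameter (m^2) of the element.  Equating this
with the tissue strain energy density W_T at the same stretch yields the
variable stiffness

    ks(lam) = 2 * nu_ij * W_T(lam) / (lam^2 - lam)        [Newtons]

which is precomputed on a dense stretch grid at initialization and looked
up (linear interpolation) inside the simulation loop.  Two branch kinds
exist: the virgin table built from W_T, and unloading tables built from
the softened energy (work integral of the softened stress from the
residual-stretch zero crossing), one per reversal stretch lam_max.

Unit convention: the constitutive module works in kPa; tables convert to
SI (Pa * m^2 = N) so that ``ks`` is in Newtons and the element force law
``F = ks * lam`` (energy-consistent convention) is in Newtons.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from scipy.integrate import cumulative_trapezoid

from eesm.constitutive import (
    DomainError,
    MaterialParams,
    residual_stretch,
    softened_stress_vec,
    uniaxial_state,
    w_total,
)

__all__ = [
    "StiffnessTable",
    "build_virgin_table",
    "build_unloading_table",
    "stiffness_at",
    "spring_energy",
    "axis_stiffness",
    "save_table",
    "load_table",
    "LIVER_NU_IJ",
]

KPA_TO_PA = 1.0e3

#: Transversal-area parameter of the liver specimens (m^2).
LIVER_NU_IJ = 3.569e-5

#: First grid node sits at 1 + _GRID_EPS; the lam -> 1 limit of the table
#: is the analytic value 0 (W_T is O((lam-1)^2) while lam^2-lam is O(lam-1)).
_GRID_EPS = 1e-6


@dataclass(frozen=True)
class StiffnessTable:
    """Precomputed (stretch, stiffness) pairs for one branch.

    ``ks_values`` are in Newtons under the energy-consistent force
    convention ``F = ks * lam``.  ``energy_values`` (Pa) store the branch
    energy density at each node; kept so the energy identity
    ``ks*lam*(lam-1)/(2 nu_ij) == W`` is testable without re-deriving W.
    """

    lam_grid: np.ndarray
    ks_values: np.ndarray
    nu_ij: float
    branch: str  # "virgin" | "unloading"
    dl: float
    lam_max: float | None = None
    energy_values: np.ndarray | None = None
    params_fingerprint: str = ""

    def __post_init__(self) -> None:
        lam = np.asarray(self.lam_grid, dtype=float)
        ks = np.asarray(self.ks_values, dtype=float)
        if lam.ndim != 1 or lam.shape != ks.shape:
            raise ValueError("lam_grid and ks_values must be matching 1-D arrays")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("lam_grid must be strictly increasing")
        if not np.all(np.isfinite(ks)) or np.any(ks < -1e-15):
            raise ValueError("stiffness values must be finite and >= 0")
        if self.branch not in ("virgin", "unloading"):
            raise ValueError(f"unknown branch {self.branch!r}")

    @property
    def lam_min(self) -> float:
        return float(self.lam_grid[0])

    @property
    def lam_hi(self) -> float:
        return float(self.lam_grid[-1])


def _make_grid(lam_max: float, dl: float) -> np.ndarray:
    if dl <= 0:
        raise ValueError(f"grid spacing dl must be positive, got {dl}")
    grid = np.arange(1.0 + _GRID_EPS, lam_max, dl)
    if grid[-1] < lam_max:
        grid = np.append(grid, lam_max)
    return grid


def build_virgin_table(
    params: MaterialParams,
    nu_ij: float,
    lam_max: float,
    dl: float = 1e-3,
) -> StiffnessTable:
    """Precompute the virgin-branch stiffness table up to ``lam_max``.

    Raises :class:`DomainError` if the grid would reach the chain lock
    stretch (lam_r >= 1).
    """
    grid = _make_grid(lam_max, dl)
    energy = np.empty_like(grid)
    for i, lam in enumerate(grid):
        energy[i] = w_total(uniaxial_state(lam, params), params)  # raises at lock
    energy_pa = energy * KPA_TO_PA
    ks = 2.0 * nu_ij * energy_pa / (grid * (grid - 1.0))
    return StiffnessTable(
        lam_grid=grid, ks_values=ks, nu_ij=nu_ij, branch="virgin",
        dl=dl, lam_max=float(lam_max), energy_values=energy_pa,
        params_fingerprint=params.fingerprint(),
    )


def build_unloading_table(
    params: MaterialParams,
    nu_ij: float,
    lam_max: float,
    dl: float = 1e-3,
) -> StiffnessTable:
    """Precompute the unloading-branch table for reversal stretch ``lam_max``.

    The softened energy is the work of the softened engineering stress
    integrated from the residual-stretch zero crossing lam_res upward;
    below lam_res the stored energy is clamped to zero so stiffness stays
    non-negative.  Integration runs on a refined grid (dl/4 plus a
    geometrically graded tail into the reversal point, where the softening
    factor has a square-root cusp) and is sampled back onto the table
    nodes.
    """
    grid = _make_grid(lam_max, dl)
    lam_res = residual_stretch(params, lam_max)
    # refined integration grid: table nodes + dl/4 + graded tail at lam_max
    fine = np.arange(lam_res, lam_max, dl / 16.0)
    tail = lam_max - (lam_max - lam_res) * 0.5 ** np.arange(1, 40)
    pts = np.unique(np.concatenate((fine, tail, grid, [lam_res, lam_max])))
    pts = pts[(pts >= lam_res) & (pts <= lam_max)]
    sig = np.asarray(softened_stress_vec(pts, lam_max, params))
    w_cum = cumulative_trapezoid(sig, pts, initial=0.0)
    energy = np.maximum(np.interp(grid, pts, w_cum, left=0.0), 0.0)
    energy[grid <= lam_res] = 0.0
    energy_pa = energy * KPA_TO_PA
    ks = 2.0 * nu_ij * energy_pa / (grid * (grid - 1.0))
    return StiffnessTable(
        lam_grid=grid, ks_values=ks, nu_ij=nu_ij, branch="unloading",
        dl=dl, lam_max=float(lam_max), energy_values=energy_pa,
        params_fingerprint=params.fingerprint(),
    )


def stiffness_at(table: StiffnessTable, lam: float) -> float:
    """Interpolated stiffness (N) at stretch ``lam``.

    Exact at grid nodes, linear in between.  Below the first node the value
    is clamped (with a warning) to the first node — the analytic limit at
    lam = 1 is 0 and the first node is within dl of it.  Above the last
    node extrapolation is refused: past the reversal stretch the table says
    nothing about the material.
    """
    lam = float(lam)
    if lam > table.lam_hi + 1e-12:
        raise DomainError(
            f"stretch {lam} beyond table range (max {table.lam_hi}); "
            "extrapolating past lam_max is unsafe"
        )
    if lam < table.lam_min:
        warnings.warn(
            f"stretch {lam} below table minimum {table.lam_min}; clamping",
            stacklevel=2,
        )
        return float(table.ks_values[0])
    return float(np.interp(lam, table.lam_grid, table.ks_values))


def spring_energy(ks: float, lam: float, nu_ij: float) -> float:
    """Stored spring energy density ``ks*lam*(lam-1)/(2*nu_ij)`` (Pa)."""
    if lam < 1.0 - 1e-12:
        raise ValueError(f"spring energy defined for lam >= 1, got {lam}")
    return ks * lam * (lam - 1.0) / (2.0 * nu_ij)


def axis_stiffness(
    table_x: StiffnessTable,
    table_y: StiffnessTable,
    table_z: StiffnessTable,
    lam: float,
):
    """Per-axis stiffness triple (ksx, ksy, ksz) at stretch ``lam``.

    For the isotropized liver model all three tables are the same object
    and the three components are equal; distinct tables give independent
    componentwise lookups.
    """
    return (
        stiffness_at(table_x, lam),
        stiffness_at(table_y, lam),
        stiffness_at(table_z, lam),
    )


# ---------------------------------------------------------------------------
# Table persistence: CSV of (lam, ks_N) plus a JSON sidecar with metadata
# ---------------------------------------------------------------------------

def save_table(table: StiffnessTable, csv_path: Union[str, Path]) -> None:
    csv_path = Path(csv_path)
    import pandas as pd

    df = pd.DataFrame({"lam": table.lam_grid, "ks_N": table.ks_values})
    if table.energy_values is not None:
        df["energy_Pa"] = table.energy_values
    # 17 significant digits: float64 round-trips exactly through the CSV
    df.to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "nu_ij_m2": table.nu_ij,
        "branch": table.branch,
        "lam_max": table.lam_max,
        "dl": table.dl,
        "params_fingerprint": table.params_fingerprint,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_table(csv_path: Union[str, Path]) -> StiffnessTable:
    csv_path = Path(csv_path)
    import pandas as pd

    df = pd.read_csv(csv_path, float_precision="round_trip")
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    energy = df["energy_Pa"].to_numpy() if "energy_Pa" in df else None
    return StiffnessTable(
        lam_grid=df["lam"].to_numpy(),
        ks_values=df["ks_N"].to_numpy(),
        nu_ij=meta["nu_ij_m2"],
        branch=meta["branch"],
        dl=meta["dl"],
        lam_max=meta["lam_max"],
        energy_values=energy,
        params_fingerprint=meta.get("params_fingerprint", ""),
    )
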