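"""Spring-mass simulation with equivalent-energy (table-driven) elements.

Every mesh edge is a one-dimensional spring whose stiffness is looked up,
at the element's current stretch, in a precomputed equivalent-energy table
(virgin branch) or in a per-reversal-stretch unloading table once the
element unloads below its historical maximum stretch (Mullins branch
selection).  Integration is semi-implicit Euler (default) or velocity
Verlet, with simple velocity damping.

Force conventions
-----------------
``energy-consistent`` (default): F = ks(lam) * lam, the form under which
the spring's stored energy density equals the tissue energy density
exactly at every tabulated stretch.  ``hooke-extension``: F =
ks(lam) * (lam - 1), the classic spring-mass form with the table value
reinterpreted as a stiffness per unit stretch.

Compression (lam < 1) is outside the table's domain; the response there is
linearized with the small-strain tangent extrapolated from the first table
nodes, which prevents unphysical zero resistance.

Mesh I/O supports OBJ (triangles) and legacy ASCII VTK unstructured grids
(triangles or tetrahedra); deformation histories are written as a VTK
legacy file series.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from eesm.constitutive import MaterialParams, LAM_R_GUARD
from eesm.stiffness import (
    LIVER_NU_IJ,
    StiffnessTable,
    build_unloading_table,
    build_virgin_table,
)
from eesm.fitting import ExperimentCurve

logger = logging.getLogger("eesm.meshsim")

__all__ = [
    "SpringMesh",
    "SimConfig",
    "SimState",
    "TableSet",
    "load_mesh",
    "save_mesh",
    "save_vtk_series",
    "element_force",
    "step",
    "run_virtual_uniaxial_test",
    "suggest_dt",
    "max_table_stretch",
]

#: Historical-maximum stretches are quantized to this resolution when used
#: as unloading-table cache keys.
LAM_HIST_QUANTUM = 1e-3

SOFT_TISSUE_DENSITY = 1060.0  # kg/m^3


# ---------------------------------------------------------------------------
# Mesh container and I/O
# ---------------------------------------------------------------------------

def _unique_edges(cells: np.ndarray) -> np.ndarray:
    """Sorted unique node pairs from triangle (n,3) or tetra (n,4) cells."""
    k = cells.shape[1]
    if k == 3:
        pairs = [(0, 1), (1, 2), (0, 2)]
    elif k == 4:
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    else:
        raise ValueError(f"cells must be triangles or tetrahedra, got {k} nodes")
    edges = np.vstack([cells[:, p] for p in pairs])
    edges = np.sort(edges, axis=1)
    uniq = np.unique(edges, axis=0)
    return uniq


@dataclass
class SpringMesh:
    """Nodes plus EESM elements (unique edges with rest lengths)."""

    positions: np.ndarray  # (n, 3) metres
    elements: np.ndarray  # (m, 2) int node pairs, i < j, unique
    rest_lengths: np.ndarray  # (m,) metres
    masses: np.ndarray  # (n,) kg
    fixed: np.ndarray  # (n,) bool
    nu_ij: float = LIVER_NU_IJ  # element transversal area, m^2
    faces: np.ndarray | None = None  # (k, 3) triangles, for round-trip I/O
    cells: np.ndarray | None = None  # (k, 4) tetrahedra
    node_tags: dict = field(default_factory=dict)  # name -> node index array

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        if np.any(self.elements[:, 0] == self.elements[:, 1]):
            raise ValueError("element endpoints must be distinct")
        key = np.sort(self.elements, axis=1)
        if len(np.unique(key, axis=0)) != len(key):
            raise ValueError("duplicate element pairs")
        if np.any(self.rest_lengths <= 0):
            raise ValueError("all rest lengths must be positive")

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @classmethod
    def from_cells(
        cls,
        positions: np.ndarray,
        cells: np.ndarray,
        nu_ij: float = LIVER_NU_IJ,
        total_mass: float | None = None,
    ) -> "SpringMesh":
        """Build a mesh from triangle or tetra connectivity.

        Duplicate cells are dropped with a warning; shared edges are merged
        into single elements.  Mass is lumped per node proportionally to
        the summed rest length of incident elements (default total 1 kg).
        """
        positions = np.asarray(positions, dtype=float)
        cells = np.asarray(cells, dtype=int)
        uniq_cells = np.unique(np.sort(cells, axis=1), axis=0)
        if len(uniq_cells) != len(cells):
            logger.warning(
                "dropped %d duplicate cells", len(cells) - len(uniq_cells)
            )
        edges = _unique_edges(uniq_cells)
        rest = np.linalg.norm(
            positions[edges[:, 1]] - positions[edges[:, 0]], axis=1
        )
        incident = np.zeros(len(positions))
        np.add.at(incident, edges[:, 0], rest)
        np.add.at(incident, edges[:, 1], rest)
        if incident.sum() == 0:
            raise ValueError("degenerate mesh: zero total edge length")
        total = 1.0 if total_mass is None else total_mass
        masses = total * incident / incident.sum()
        mesh = cls(
            positions=positions,
            elements=edges,
            rest_lengths=rest,
            masses=masses,
            fixed=np.zeros(len(positions), dtype=bool),
            nu_ij=nu_ij,
            faces=uniq_cells if cells.shape[1] == 3 else None,
            cells=uniq_cells if cells.shape[1] == 4 else None,
        )
        logger.info(
            "mesh: %d nodes, %d elements", mesh.n_nodes, mesh.n_elements
        )
        return mesh


def load_mesh(path: Union[str, Path], nu_ij: float = LIVER_NU_IJ) -> SpringMesh:
    """Read an OBJ (triangles) or legacy-ASCII VTK (tris/tets) mesh."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".obj":
        verts, cells = _read_obj(path)
    elif suffix == ".vtk":
        verts, cells = _read_vtk_legacy(path)
    else:
        raise ValueError(f"unsupported mesh format {suffix!r} (use .obj or .vtk)")
    return SpringMesh.from_cells(verts, cells, nu_ij=nu_ij)


def save_mesh(mesh: SpringMesh, path: Union[str, Path]) -> None:
    """Write the mesh connectivity back to OBJ or legacy VTK."""
    path = Path(path)
    if path.suffix.lower() == ".obj":
        if mesh.faces is None:
            raise ValueError("mesh has no triangle faces; write .vtk instead")
        _write_obj(path, mesh.positions, mesh.faces)
    elif path.suffix.lower() == ".vtk":
        cells = mesh.cells if mesh.cells is not None else mesh.faces
        if cells is None:
            raise ValueError("mesh has neither tetrahedra nor triangles")
        _write_vtk_legacy(path, mesh.positions, cells)
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")


def _read_obj(path: Path):
    verts, faces = [], []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        try:
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(tok.split("/")[0]) - 1 for tok in parts[1:]]
                if len(idx) != 3:
                    raise ValueError("only triangular faces supported")
                faces.append(idx)
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{ln}: cannot parse {line!r}: {exc}") from exc
    if not verts or not faces:
        raise ValueError(f"{path}: no vertices/faces found")
    return np.array(verts), np.array(faces, dtype=int)


def _write_obj(path: Path, verts: np.ndarray, faces: np.ndarray) -> None:
    lines = [f"v {x:.9g} {y:.9g} {z:.9g}" for x, y, z in verts]
    lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in faces]
    path.write_text("\n".join(lines) + "\n")


_VTK_CELL_TYPES = {3: 5, 4: 10}  # nodes per cell -> VTK cell type id


def _read_vtk_legacy(path: Path):
    lines = path.read_text().splitlines()
    i, verts, cells = 0, None, []
    try:
        while i < len(lines):
            parts = lines[i].split()
            if parts[:1] == ["POINTS"]:
                n = int(parts[1])
                nums = []
                i += 1
                while len(nums) < 3 * n:
                    nums.extend(float(x) for x in lines[i].split())
                    i += 1
                verts = np.array(nums).reshape(n, 3)
                continue
            if parts[:1] == ["CELLS"]:
                n = int(parts[1])
                i += 1
                for _ in range(n):
                    row = [int(x) for x in lines[i].split()]
                    if row[0] != len(row) - 1:
                        raise ValueError(f"bad cell row {lines[i]!r}")
                    cells.append(row[1:])
                    i += 1
                continue
            i += 1
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}:{i + 1}: cannot parse VTK file: {exc}") from exc
    if verts is None or not cells:
        raise ValueError(f"{path}: no POINTS/CELLS sections found")
    sizes = {len(c) for c in cells}
    if len(sizes) != 1 or sizes.pop() not in (3, 4):
        raise ValueError(f"{path}: mixed or unsupported cell sizes")
    return verts, np.array(cells, dtype=int)


def _write_vtk_legacy(path: Path, verts: np.ndarray, cells: np.ndarray) -> None:
    k = cells.shape[1]
    out = [
        "# vtk DataFile Version 3.0",
        "eesm mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(verts)} double",
    ]
    out += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in verts]
    out.append(f"CELLS {len(cells)} {len(cells) * (k + 1)}")
    out += [f"{k} " + " ".join(str(v) for v in row) for row in cells]
    out.append(f"CELL_TYPES {len(cells)}")
    out += [str(_VTK_CELL_TYPES[k])] * len(cells)
    path.write_text("\n".join(out) + "\n")


def save_vtk_series(
    mesh: SpringMesh, snapshots: list, out_dir: Union[str, Path], stem: str = "frame"
) -> list:
    """Write per-frame node positions as numbered legacy VTK files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cells = mesh.cells if mesh.cells is not None else mesh.faces
    if cells is None:  # fall back to edges as VTK lines is overkill; use points
        raise ValueError("mesh has no cells to write")
    paths = []
    for i, pos in enumerate(snapshots):
        p = out_dir / f"{stem}_{i:05d}.vtk"
        _write_vtk_legacy(p, np.asarray(pos), cells)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Stiffness-table set with Mullins branch caching
# ---------------------------------------------------------------------------

def max_table_stretch(params: MaterialParams, margin: float = 0.999) -> float:
    """Largest axial stretch below the chain lock stretch.

    Solves I1(lam)/3 = N * (margin * guard)^2 by bisection.
    """
    target = 3.0 * params.N * (margin * LAM_R_GUARD) ** 2
    lo, hi = 1.0, 1.0
    while hi**2 + 2.0 / hi < target:
        hi *= 1.5
        if hi > 1e6:
            return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid**2 + 2.0 / mid < target:
            lo = mid
        else:
            hi = mid
    return lo


class TableSet:
    """Virgin table plus lazily-built unloading tables keyed by reversal stretch.

    Reversal stretches are quantized to :data:`LAM_HIST_QUANTUM` so that an
    element never sees an unloading table whose lam_max is below its
    recorded historical maximum (keys round up).
    """

    def __init__(
        self,
        params: MaterialParams,
        nu_ij: float,
        lam_max: float,
        dl: float = 1e-3,
    ) -> None:
        self.params = params
        self.nu_ij = nu_ij
        self.lam_max = float(lam_max)
        self.dl = dl
        self.virgin = build_virgin_table(params, nu_ij, lam_max, dl)
        self._unloading: dict[int, StiffnessTable] = {}
        # small-strain tangent dF/dlam for the linearized compression branch,
        # estimated from the first table nodes of F = ks * lam
        g = self.virgin.lam_grid
        F = self.virgin.ks_values * g
        i1 = min(10, len(g) - 1)
        self._k_compress = (F[i1] - F[0]) / (g[i1] - g[0])
        self._warned_compression = False

    def _key(self, lam_hist: float) -> int:
        return int(np.ceil(lam_hist / LAM_HIST_QUANTUM - 1e-9))

    def unloading_for(self, lam_hist: float) -> StiffnessTable:
        key = self._key(lam_hist)
        if key not in self._unloading:
            lmax = key * LAM_HIST_QUANTUM
            self._unloading[key] = build_unloading_table(
                self.params, self.nu_ij, lmax, self.dl
            )
        return self._unloading[key]

    def virgin_force_potential(self):
        """Work integral of the virgin force law on the table grid.

        Returns (U_grid, grid) with U in J per metre of rest length,
        U(grid[0]) = 0 (the first node sits at 1 + 1e-6).
        """
        if not hasattr(self, "_u_cache"):
            from scipy.integrate import cumulative_trapezoid

            g = self.virgin.lam_grid
            F = self.virgin.ks_values * g
            self._u_cache = (cumulative_trapezoid(F, g, initial=0.0), g)
        return self._u_cache

    def tangent_stiffness(self) -> float:
        """Max dF/dlam over the virgin table (for time-step heuristics)."""
        g = self.virgin.lam_grid
        F = self.virgin.ks_values * g
        return float(np.max(np.diff(F) / np.diff(g)))

    def force_magnitudes(
        self, lam: np.ndarray, lam_hist: np.ndarray, convention: str
    ) -> np.ndarray:
        """Axial force (N) for arrays of stretches and historical maxima."""
        lam = np.asarray(lam, dtype=float)
        lam_hist = np.asarray(lam_hist, dtype=float)
        F = np.empty_like(lam)
        comp = lam < 1.0
        if comp.any():
            if not self._warned_compression:
                logger.warning(
                    "%d element(s) in compression; using linearized response",
                    int(comp.sum()),
                )
                self._warned_compression = True
            F[comp] = self._k_compress * (lam[comp] - 1.0)
        tens = ~comp
        # virgin: at or above historical max (within one quantum)
        virgin_sel = tens & (lam >= lam_hist - LAM_HIST_QUANTUM)
        if virgin_sel.any():
            ks = self._interp(self.virgin, lam[virgin_sel])
            F[virgin_sel] = self._apply_convention(ks, lam[virgin_sel], convention)
        unload_sel = tens & ~virgin_sel
        if unload_sel.any():
            keys = np.array([self._key(h) for h in lam_hist[unload_sel]])
            vals = np.empty(int(unload_sel.sum()))
            for key in np.unique(keys):
                tab = self.unloading_for(key * LAM_HIST_QUANTUM)
                pick = keys == key
                ks = self._interp(tab, lam[unload_sel][pick])
                vals[pick] = self._apply_convention(
                    ks, lam[unload_sel][pick], convention
                )
            F[unload_sel] = vals
        return F

    @staticmethod
    def _interp(tab: StiffnessTable, lam: np.ndarray) -> np.ndarray:
        """Table lookup extended by the analytic limit ks(1) = 0.

        Between lam = 1 and the first node (1 + 1e-6) the stiffness is
        interpolated toward the exact rest value 0, so an element at rest
        length exerts exactly zero force.  Above the last node the value is
        clamped (transient overshoots during dynamics), unlike the strict
        user-facing :func:`eesm.stiffness.stiffness_at`.
        """
        lam = np.minimum(lam, tab.lam_hi)
        return np.interp(
            lam,
            np.concatenate(([1.0], tab.lam_grid)),
            np.concatenate(([0.0], tab.ks_values)),
        )

    @staticmethod
    def _apply_convention(ks, lam, convention: str):
        if convention == "energy-consistent":
            return ks * lam
        if convention == "hooke-extension":
            return ks * (lam - 1.0)
        raise ValueError(f"unknown force convention {convention!r}")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Integrator settings.  The model itself fixes none of these."""

    dt: float = 1e-3  # s
    damping: float = 0.0  # 1/s velocity damping coefficient
    integrator: str = "semi-implicit-euler"  # | "verlet"
    max_steps: int = 10_000
    gravity: np.ndarray | None = None  # m/s^2, e.g. (0, 0, -9.81)
    force_convention: str = "energy-consistent"  # | "hooke-extension"
    # disable Mullins history tracking (pure virgin hyperelastic springs);
    # used by energy-conservation checks where softening would dissipate
    track_history: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.damping < 0:
            raise ValueError(f"damping must be >= 0, got {self.damping}")
        if self.integrator not in ("semi-implicit-euler", "verlet"):
            raise ValueError(f"unknown integrator {self.integrator!r}")


@dataclass
class SimState:
    """Mutable simulation state (positions, velocities, Mullins history)."""

    positions: np.ndarray
    velocities: np.ndarray
    lam_hist: np.ndarray  # per-element historical maximum stretch
    step_index: int = 0
    lam_current: np.ndarray | None = None
    frame_ms: list = field(default_factory=list)

    @classmethod
    def from_mesh(cls, mesh: SpringMesh) -> "SimState":
        return cls(
            positions=mesh.positions.copy(),
            velocities=np.zeros_like(mesh.positions),
            lam_hist=np.ones(mesh.n_elements),
        )


def suggest_dt(mesh: SpringMesh, tables: TableSet, safety: float = 0.1) -> float:
    """Stable time step heuristic from max tangent stiffness and min mass.

    dt = safety * 2 / omega_max with omega_max = sqrt(k_max / m_min) and
    k_max = max dF/dlam / min rest length (N/m).
    """
    k_max = tables.tangent_stiffness() / float(np.min(mesh.rest_lengths))
    m_min = float(np.min(mesh.masses))
    omega = np.sqrt(max(k_max, 1e-30) / m_min)
    return safety * 2.0 / omega


def _assemble_forces(
    state: SimState, mesh: SpringMesh, tables: TableSet, config: SimConfig
):
    """Per-node force array (N); also returns per-element stretches."""
    i, j = mesh.elements[:, 0], mesh.elements[:, 1]
    d = state.positions[j] - state.positions[i]
    lengths = np.linalg.norm(d, axis=1)
    if np.any(lengths <= 0) or not np.all(np.isfinite(lengths)):
        bad = int(np.argmin(np.where(np.isfinite(lengths), lengths, -np.inf)))
        raise RuntimeError(
            f"element {bad} (nodes {i[bad]}-{j[bad]}) has degenerate length "
            f"{lengths[bad]}; simulation unstable — try a smaller dt"
        )
    lam = lengths / mesh.rest_lengths
    mags = tables.force_magnitudes(lam, state.lam_hist, config.force_convention)
    unit = d / lengths[:, None]
    fvec = mags[:, None] * unit  # force on node i, along i -> j
    forces = np.zeros_like(state.positions)
    np.add.at(forces, i, fvec)
    np.add.at(forces, j, -fvec)
    if config.gravity is not None:
        forces += mesh.masses[:, None] * np.asarray(config.gravity)
    return forces, lam


def element_force(
    p_i: np.ndarray,
    p_j: np.ndarray,
    rest_length: float,
    tables: TableSet,
    lam_hist: float = 1.0,
    convention: str = "energy-consistent",
) -> np.ndarray:
    """Force vector on node i from a single element.

    The branch is chosen by the current stretch against the historical
    maximum: virgin at or above it, the unloading table for ``lam_hist``
    below it.  Equal and opposite force acts on node j.
    """
    d = np.asarray(p_j, dtype=float) - np.asarray(p_i, dtype=float)
    length = float(np.linalg.norm(d))
    if length <= 0:
        raise ValueError("coincident element endpoints")
    lam = length / rest_length
    mag = tables.force_magnitudes(
        np.array([lam]), np.array([lam_hist]), convention
    )[0]
    return mag * d / length


def step(
    state: SimState, mesh: SpringMesh, tables: TableSet, config: SimConfig
) -> SimState:
    """Advance one time step in place (also returns the state).

    Fixed nodes stay immobile; per-element historical maxima are updated;
    wall-clock frame time (ms) is appended to the state's log.
    """
    t0 = time.perf_counter()
    free = ~mesh.fixed
    inv_m = 1.0 / mesh.masses[:, None]

    if config.integrator == "semi-implicit-euler":
        forces, lam = _assemble_forces(state, mesh, tables, config)
        acc = forces * inv_m - config.damping * state.velocities
        state.velocities[free] += config.dt * acc[free]
        state.velocities[mesh.fixed] = 0.0
        state.positions[free] += config.dt * state.velocities[free]
    else:  # velocity Verlet
        forces, lam = _assemble_forces(state, mesh, tables, config)
        acc = forces * inv_m - config.damping * state.velocities
        half_v = state.velocities + 0.5 * config.dt * acc
        half_v[mesh.fixed] = 0.0
        state.positions[free] += config.dt * half_v[free]
        forces2, lam = _assemble_forces(state, mesh, tables, config)
        acc2 = forces2 * inv_m - config.damping * half_v
        state.velocities = half_v + 0.5 * config.dt * acc2
        state.velocities[mesh.fixed] = 0.0

    if not np.all(np.isfinite(state.positions)):
        bad_node = int(np.argmax(~np.isfinite(state.positions).all(axis=1)))
        raise RuntimeError(
            f"non-finite position at node {bad_node} after step "
            f"{state.step_index}; reduce dt (current {config.dt})"
        )
    if config.track_history:
        state.lam_hist = np.maximum(state.lam_hist, lam)
    state.lam_current = lam
    state.step_index += 1
    state.frame_ms.append((time.perf_counter() - t0) * 1e3)
    return state


def spring_potential(state: SimState, mesh: SpringMesh, tables: TableSet) -> float:
    """Total elastic potential (J) of the virgin force law.

    The table force F = ks(lam)*lam depends only on the element stretch, so
    on the virgin branch it is conservative with potential
    ``U(lam) = L * integral_1^lam F(x) dx`` (work along the element axis);
    the compression branch contributes the quadratic of its linear tangent.
    Used by energy-conservation checks (with Mullins history tracking off).
    """
    i, j = mesh.elements[:, 0], mesh.elements[:, 1]
    d = state.positions[j] - state.positions[i]
    lam = np.linalg.norm(d, axis=1) / mesh.rest_lengths
    u_grid, grid = tables.virgin_force_potential()
    u = np.where(
        lam >= 1.0,
        np.interp(np.clip(lam, grid[0], grid[-1]), grid, u_grid),
        0.5 * tables._k_compress * (lam - 1.0) ** 2,
    )
    return float(np.sum(u * mesh.rest_lengths))


def kinetic_energy(state: SimState, mesh: SpringMesh) -> float:
    return float(0.5 * np.sum(mesh.masses * np.sum(state.velocities**2, axis=1)))


# ---------------------------------------------------------------------------
# Virtual uniaxial tension test
# ---------------------------------------------------------------------------

def _solve_static(
    state: SimState,
    mesh: SpringMesh,
    tables: TableSet,
    config: SimConfig,
    free_idx: np.ndarray,
) -> None:
    """Find static equilibrium of the free nodes at frozen Mullins history."""
    from scipy.optimize import root

    x0 = state.positions[free_idx].ravel().copy()

    def residual(x):
        state.positions[free_idx] = x.reshape(-1, 3)
        forces, _ = _assemble_forces(state, mesh, tables, config)
        return forces[free_idx].ravel()

    sol = root(residual, x0, method="hybr", tol=1e-12)
    state.positions[free_idx] = sol.x.reshape(-1, 3)
    if not sol.success:
        resid = np.max(np.abs(residual(sol.x)))
        if resid > 1e-6:
            raise RuntimeError(
                f"static equilibrium solve did not converge (residual {resid:.2e} N)"
            )
    state.velocities[free_idx] = 0.0

def run_virtual_uniaxial_test(
    mesh: SpringMesh,
    params: MaterialParams,
    lam_target: float,
    n_increments: int = 30,
    config: SimConfig | None = None,
    axis: int = 0,
    solver: str = "static",
    relax_steps: int = 4000,
    force_tol: float = 1e-8,
    table_margin: float = 1.05,
    cycle: int = 1,
) -> ExperimentCurve:
    """Quasi-static loading/unloading tension test on a beam-like mesh.

    Nodes tagged ``fixed`` are clamped; nodes tagged ``driven`` are moved
    so that the driven face's coordinate along ``axis`` is scaled by the
    applied stretch, ramped 1 -> lam_target -> 1.  A quasi-static test is
    a sequence of equilibria: with ``solver="static"`` (default) each
    increment's equilibrium of the free nodes is found by a Newton-type
    root solve on the nodal forces (warm-started from an affine predictor);
    ``solver="dynamic"`` instead relaxes with damped time stepping through
    :func:`step` until residual force and kinetic energy are negligible.
    The reaction force on the driven face is recorded as engineering
    stress ``F_reaction / (n_driven * nu_ij)``; Mullins history is updated
    from converged stretches only.

    Returns a two-branch :class:`~eesm.fitting.ExperimentCurve`; the
    enclosed loop area is the dissipated (Mullins) energy density.
    """
    if "fixed" not in mesh.node_tags or "driven" not in mesh.node_tags:
        raise ValueError("mesh needs 'fixed' and 'driven' node tags")
    fixed_ids = np.asarray(mesh.node_tags["fixed"], dtype=int)
    driven_ids = np.asarray(mesh.node_tags["driven"], dtype=int)

    lam_table = min(lam_target * table_margin,
                    max_table_stretch(params) * 0.999)
    if lam_table <= lam_target:
        raise ValueError(
            f"lam_target {lam_target} too close to the lock stretch"
        )
    tables = TableSet(params, mesh.nu_ij, lam_table)

    mesh.fixed[:] = False
    mesh.fixed[fixed_ids] = True
    mesh.fixed[driven_ids] = True
    state = SimState.from_mesh(mesh)

    if config is None:
        dt = suggest_dt(mesh, tables)
        # near-critical damping of the stiffest mode for fast settling
        k_max = tables.tangent_stiffness() / float(np.min(mesh.rest_lengths))
        omega = np.sqrt(k_max / float(np.min(mesh.masses)))
        config = SimConfig(dt=dt, damping=omega)

    ref0 = mesh.positions.copy()
    up = np.linspace(1.0, lam_target, n_increments + 1)[1:]
    down = np.linspace(lam_target, 1.0, n_increments + 1)[1:]
    schedule = [(l, "loading") for l in up] + [(l, "unloading") for l in down]

    rows = []
    origin = ref0[fixed_ids, axis].mean()
    free = ~mesh.fixed
    free_idx = np.where(free)[0]
    lam_prev = 1.0
    for lam_app, branch_label in schedule:
        state.positions[driven_ids, axis] = (
            origin + (ref0[driven_ids, axis] - origin) * lam_app
        )
        state.velocities[driven_ids] = 0.0
        if free.any():
            if solver == "static":
                # affine predictor: scale free-node axial coordinates
                state.positions[free_idx, axis] = origin + (
                    state.positions[free_idx, axis] - origin
                ) * (lam_app / lam_prev)
                _solve_static(state, mesh, tables, config, free_idx)
            elif solver == "dynamic":
                for it in range(relax_steps):
                    step(state, mesh, tables, config)
                    if it % 20 == 19:
                        forces, _ = _assemble_forces(state, mesh, tables, config)
                        resid = np.max(np.abs(forces[free]))
                        vmax = np.max(np.abs(state.velocities[free]))
                        ke = kinetic_energy(state, mesh)
                        pot = spring_potential(state, mesh, tables)
                        if (resid < force_tol and vmax < 1e-9) or (
                            pot > 0 and ke < 1e-6 * pot and resid < force_tol * 1e3
                        ):
                            break
            else:
                raise ValueError(f"unknown solver {solver!r}")
        lam_prev = lam_app
        forces, lam_el = _assemble_forces(state, mesh, tables, config)
        state.lam_hist = np.maximum(state.lam_hist, lam_el)
        # reaction on the driven face = - internal force on driven nodes
        reaction = -float(np.sum(forces[driven_ids, axis]))
        area = len(driven_ids) * mesh.nu_ij
        rows.append(
            {
                "lam": lam_app,
                "stress_kPa": reaction / area / 1e3,
                "branch": branch_label,
                "cycle": cycle,
            }
        )
    import pandas as pd

    curve = ExperimentCurve(
        data=pd.DataFrame(rows),
        metadata={
            "source": "virtual_uniaxial_test",
            "lam_target": lam_target,
            "lam_table": lam_table,
            "n_elements": mesh.n_elements,
            "force_convention": config.force_convention,
        },
    )
    return curve
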