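"""Synthetic uniaxial test curves and fixture meshes.

The cyclic-test generator emulates quasi-static loading/unloading tension
tests on soft-tissue specimens: three cycles to increasing maximum
stretches (default 1.15, 1.23, 1.30), nonlinear stiffening loading
branches, softened unloading branches that reach zero stress at a positive
residual stretch, and multiplicative lognormal measurement noise.  All
stresses come from the package's own constitutive law, so noiseless curves
satisfy exactly the properties the analytic model does.

Mesh generators provide a regular beam lattice (for virtual tension tests)
and a subdivided-icosahedron ellipsoid surface (an organ-scale stand-in).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from eesm.constitutive import (
    DomainError,
    MaterialParams,
    residual_stretch,
)
from eesm.fitting import ExperimentCurve, predict_curve
from eesm.meshsim import SpringMesh, max_table_stretch
from eesm.stiffness import LIVER_NU_IJ

__all__ = [
    "SynthConfig",
    "gen_uniaxial_cycles",
    "gen_beam_mesh",
    "gen_ellipsoid_mesh",
    "single_element_mesh",
]

#: Canonical cycle reversal stretches of the liver test protocol.
DEFAULT_CYCLE_LAM_MAXES = (1.15, 1.23, 1.30)


@dataclass
class SynthConfig:
    """Settings for the cyclic-test generator."""

    params: MaterialParams
    cycle_lam_maxes: tuple = DEFAULT_CYCLE_LAM_MAXES
    points_per_branch: int = 100
    noise_cv: float = 0.02  # coefficient of variation of multiplicative noise
    seed: int = 0
    noise_model: str = "lognormal"  # | "additive"

    def __post_init__(self) -> None:
        maxes = np.asarray(self.cycle_lam_maxes, dtype=float)
        if np.any(np.diff(maxes) <= 0):
            raise ValueError("cycle maxima must be strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.noise_model not in ("lognormal", "additive"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def gen_uniaxial_cycles(config: SynthConfig) -> ExperimentCurve:
    """Generate a cyclic loading/unloading stress-stretch curve.

    Each cycle loads to its reversal stretch (reloading below the previous
    cycle's maximum follows the softened branch, above it the virgin law)
    and unloads back down to the residual stretch, where the softened
    stress crosses zero.  Noise is i.i.d. mean-one lognormal with the
    requested coefficient of variation (or additive Gaussian scaled to the
    RMS clean stress).  Bit-reproducible for a fixed seed.
    """
    params = config.params
    lock = max_table_stretch(params)
    if max(config.cycle_lam_maxes) >= lock:
        raise DomainError(
            f"cycle maximum {max(config.cycle_lam_maxes)} at or beyond the "
            f"lock stretch (max usable {lock:.4f})"
        )
    npts = config.points_per_branch
    rows = []
    start = 1.0
    for cyc, lam_max in enumerate(config.cycle_lam_maxes, start=1):
        lam_load = np.linspace(start, lam_max, npts)
        lam_res = residual_stretch(params, lam_max)
        lam_unload = np.linspace(lam_max, lam_res, npts)
        rows.append(pd.DataFrame(
            {"lam": lam_load, "branch": "loading", "cycle": cyc}
        ))
        rows.append(pd.DataFrame(
            {"lam": lam_unload, "branch": "unloading", "cycle": cyc}
        ))
        start = lam_res  # reloading resumes from the residual stretch
    schedule = pd.concat(rows, ignore_index=True)
    curve = predict_curve(params, schedule)
    clean = curve.data["stress_kPa"].to_numpy()

    rng = np.random.default_rng(config.seed)
    if config.noise_cv > 0:
        if config.noise_model == "lognormal":
            s = np.sqrt(np.log1p(config.noise_cv**2))
            noise = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=len(clean))
            noisy = clean * noise
        else:
            sd = config.noise_cv * float(np.sqrt(np.mean(clean**2)))
            noisy = clean + rng.normal(0.0, sd, size=len(clean))
    else:
        noisy = clean
    data = curve.data.copy()
    data["stress_kPa"] = noisy
    return ExperimentCurve(
        data=data,
        metadata={
            "source": "synthetic",
            "seed": config.seed,
            "noise_cv": config.noise_cv,
            "noise_model": config.noise_model,
            "cycle_lam_maxes": list(config.cycle_lam_maxes),
            **params.to_dict(),
        },
    )


# ---------------------------------------------------------------------------
# Fixture meshes
# ---------------------------------------------------------------------------

def gen_beam_mesh(
    nx: int,
    ny: int,
    nz: int,
    spacing: float = 0.01,
    diagonals: bool = True,
    nu_ij: float = LIVER_NU_IJ,
    total_mass: float = 1e-3,
) -> SpringMesh:
    """Regular lattice beam of (nx, ny, nz) cells along x, y, z.

    Elements are the axis-aligned lattice edges plus (optionally) both
    face diagonals of every lattice face; rest lengths are ``spacing`` and
    ``spacing * sqrt(2)``.  The x = 0 face is tagged ``fixed`` and the
    x = nx*spacing face ``driven`` for virtual tension tests.  Node
    ordering is deterministic (x fastest).
    """
    if min(nx, ny, nz) < 1:
        raise ValueError("lattice dimensions must be >= 1")
    xs = np.arange(nx + 1) * spacing
    ys = np.arange(ny + 1) * spacing
    zs = np.arange(nz + 1) * spacing
    idx = lambda i, j, k: i + (nx + 1) * (j + (ny + 1) * k)
    positions = np.array(
        [[xs[i], ys[j], zs[k]]
         for k in range(nz + 1) for j in range(ny + 1) for i in range(nx + 1)]
    )
    edges = set()

    def add(a, b):
        edges.add((min(a, b), max(a, b)))

    for k in range(nz + 1):
        for j in range(ny + 1):
            for i in range(nx + 1):
                a = idx(i, j, k)
                if i < nx:
                    add(a, idx(i + 1, j, k))
                if j < ny:
                    add(a, idx(i, j + 1, k))
                if k < nz:
                    add(a, idx(i, j, k + 1))
                if diagonals:
                    if i < nx and j < ny:  # xy faces
                        add(idx(i, j, k), idx(i + 1, j + 1, k))
                        add(idx(i + 1, j, k), idx(i, j + 1, k))
                    if i < nx and k < nz:  # xz faces
                        add(idx(i, j, k), idx(i + 1, j, k + 1))
                        add(idx(i + 1, j, k), idx(i, j, k + 1))
                    if j < ny and k < nz:  # yz faces
                        add(idx(i, j, k), idx(i, j + 1, k + 1))
                        add(idx(i, j + 1, k), idx(i, j, k + 1))

    elements = np.array(sorted(edges), dtype=int)
    rest = np.linalg.norm(
        positions[elements[:, 1]] - positions[elements[:, 0]], axis=1
    )
    incident = np.zeros(len(positions))
    np.add.at(incident, elements[:, 0], rest)
    np.add.at(incident, elements[:, 1], rest)
    masses = total_mass * incident / incident.sum()
    mesh = SpringMesh(
        positions=positions,
        elements=elements,
        rest_lengths=rest,
        masses=masses,
        fixed=np.zeros(len(positions), dtype=bool),
        nu_ij=nu_ij,
    )
    x = positions[:, 0]
    mesh.node_tags["fixed"] = np.where(np.isclose(x, 0.0))[0]
    mesh.node_tags["driven"] = np.where(np.isclose(x, nx * spacing))[0]
    return mesh


def single_element_mesh(
    rest_length: float = 0.01,
    nu_ij: float = LIVER_NU_IJ,
    mass: float = 1e-3,
) -> SpringMesh:
    """Two nodes joined by one element along x; fixture for element tests."""
    mesh = SpringMesh(
        positions=np.array([[0.0, 0.0, 0.0], [rest_length, 0.0, 0.0]]),
        elements=np.array([[0, 1]]),
        rest_lengths=np.array([rest_length]),
        masses=np.array([mass, mass]),
        fixed=np.zeros(2, dtype=bool),
        nu_ij=nu_ij,
    )
    mesh.node_tags["fixed"] = np.array([0])
    mesh.node_tags["driven"] = np.array([1])
    return mesh


def gen_ellipsoid_mesh(
    subdivisions: int = 3,
    radii: tuple = (0.08, 0.05, 0.04),
    nu_ij: float = LIVER_NU_IJ,
    density: float = 1060.0,
) -> SpringMesh:
    """Ellipsoidal surface mesh from a subdivided icosahedron.

    ``subdivisions = 0`` gives the icosahedron (12 vertices, 30 edges);
    each level quadruples the face count.  Vertices are scaled to the
    given semi-axes (metres); total mass is density times the ellipsoid
    volume (a solid-organ stand-in lumped onto the surface nodes).
    """
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(ico.vertices) * np.asarray(radii)
    faces = np.asarray(ico.faces, dtype=int)
    volume = 4.0 / 3.0 * np.pi * float(np.prod(radii))
    return SpringMesh.from_cells(
        verts, faces, nu_ij=nu_ij, total_mass=density * volume
    )
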