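# eesm — equivalent-energy spring model for real-time soft-tissue simulation

Classic spring–mass models are fast enough for real-time surgical
simulation but linear: they cannot reproduce the strain-stiffening,
stress-softening (Mullins effect) behaviour of soft organs under large
deformation. Full hyperelastic constitutive models capture that behaviour
but are too expensive to evaluate inside an interactive loop.

`eesm` implements the hybrid between the two: a **one-dimensional spring
whose stiffness varies with stretch so that its stored energy equals the
tissue's strain energy density at every stretch**. The energy density is a
mixture of a non-Gaussian (inverse-Langevin, finite-extensibility) matrix
term and an isotropized fibre term,

    W_T = (1 − f)·W_iso + f·W_aniso
    W_iso  = µ[N(βλ_r + ln(β/sinh β)) − ln(βλ_r)] + c,   β = 3λ_r/(1 − λ_r³)
    W_aniso = (A₁/3)(I₁ − 3) + (A₂/9)(I₁ − 3)²           (incompressible)

and the equivalent spring stiffness is

    k_s(λ) = 2ν_ij · W_T(λ) / (λ² − λ),

precomputed into a lookup table at initialization so that the simulation
loop only does table lookups. Unloading below the historical maximum
stretch follows a Mullins-softened branch,
σ_s = {σ-difference + residual-strain term}·e^(−b√(M−m))·√(m/M), which
reproduces stress softening and positive residual stretches; one
unloading table is cached per reversal stretch reached.

The package covers the full pipeline for whoever needs nonlinear tissue
behaviour at spring–mass cost (surgical-simulation developers,
biomechanics students, anyone fitting uniaxial tissue data):

- `eesm.constitutive` — energies, closed-form virgin/softened stresses,
  inverse-Langevin machinery, independent numeric-derivative oracle;
- `eesm.stiffness` — equivalent-energy stiffness tables (virgin +
  unloading) with CSV/JSON persistence;
- `eesm.meshsim` — spring–mass simulator (OBJ / legacy-VTK meshes,
  semi-implicit Euler or velocity Verlet, Mullins branch selection per
  element, quasi-static virtual tension tests);
- `eesm.fitting` — parameter estimation from cyclic loading/unloading
  curves with multi-start bounded least squares and R² scoring;
- `eesm.synthdata` — synthetic cyclic test curves and fixture meshes;
- `eesm.cli` — `eesm synth | fit | table | simulate | validate`.

The built-in `LIVER_PARAMS` are constants for porcine liver parenchyma
from cyclic uniaxial tension tests: µ = 0.1 kPa, N = 1.1974, b = 3.3389,
A₁ = 9.6754 kPa, A₂ = 7543.6 kPa, C = 9.5273 kPa, f = 0.2755, with
element transversal area ν_ij = 3.569×10⁻⁵ m².

## Worked example

```python
import numpy as np
import eesm

p = eesm.LIVER_PARAMS

# 1. initialization phase: precompute the equivalent-energy table
table = eesm.build_virgin_table(p, eesm.LIVER_NU_IJ, lam_max=1.3)
print("ks(1.15) =", round(eesm.stiffness_at(table, 1.15), 6), "N")
print("ks(1.30) =", round(eesm.stiffness_at(table, 1.30), 6), "N")
print("sigma_virgin(1.3) =", round(eesm.virgin_stress(1.3, p).sigma, 2), "kPa")
print("lam_res =", round(eesm.residual_stretch(p, 1.3), 4))

# 2. fit the model to a synthetic three-cycle test (2% noise)
cfg = eesm.SynthConfig(params=p, noise_cv=0.02, seed=7, points_per_branch=67)
curve = eesm.gen_uniaxial_cycles(cfg)
fit = eesm.fit_material_params(curve, eesm.FitOptions(n_starts=20, seed=42))
print("r2_loading =", round(fit.r2_loading, 4),
      " r2_unloading =", round(fit.r2_unloading, 4))

# 3. virtual tension test of one EESM element to lam = 1.3 and back
mesh = eesm.single_element_mesh()
vt = eesm.run_virtual_uniaxial_test(mesh, p, 1.3, n_increments=15).data
load, unload = vt[vt.branch == "loading"], vt[vt.branch == "unloading"]
area = (np.trapezoid(load["stress_kPa"], load["lam"])
        + np.trapezoid(unload["stress_kPa"], unload["lam"]))
print("hysteresis area =", round(area, 3), "kPa")
```

prints

```
ks(1.15) = 0.385957 N
ks(1.30) = 2.243916 N
sigma_virgin(1.3) = 150.76 kPa
lam_res = 1.0469
r2_loading = 0.9995  r2_unloading = 0.9994
hysteresis area = 5.349 kPa
```

The stiffness values are the spring constants (newtons, force law
F = k_s·λ) that make a single spring store exactly the tissue energy
density at those stretches; `lam_res` is the residual stretch where the
softened unloading stress crosses zero (permanent set after loading to
λ = 1.3); the positive loop area is the energy density dissipated by
Mullins softening over one load/unload cycle.

The same steps are available from the shell:

```sh
eesm synth --seed 7 --out curve.csv
eesm fit --curve curve.csv --out fit.json
eesm table --area 3.569e-5 --lmax 1.3 --out table.csv
eesm simulate --mesh organ.obj --fix z+ --pull x:1.2 --out-dir run/
eesm validate
```

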