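# Methods

## Model

Soft tissue (the reference material is porcine liver parenchyma) is treated
as an incompressible composite: an isotropic matrix obeying non-Gaussian
(finite-extensibility) chain statistics, plus a fibre contribution carried
by an *isotropized* polynomial term. The total strain energy density is a
rule of mixtures

W_T = (1 − f)·W_iso + f·W_aniso,

with

- W_iso(λ_r) = µ[N(βλ_r + ln(β/sinh β)) − ln(βλ_r)] + c, where
  λ_chain = √(I₁/3), λ_r = λ_chain/√N, and β is the inverse Langevin
  function of λ_r evaluated with the Puso approximation
  β = 3λ_r/(1 − λ_r³). The constant c is fixed so that W_iso(λ=1) = 0
  (zero rest energy; the source material leaves c unspecified).
- W_aniso = (A₁/3)(I₁ − 3) + (A₂/9)(I₁ − 3)² − (2A₁/3)·ln √I₃, whose log
  term vanishes under incompressibility (I₃ = 1).

Only uniaxial, incompressible kinematics are supported:
λ₁ = λ, λ₂ = λ₃ = λ^(−1/2). Hydrostatic pressure is never represented
numerically; the uniaxial stress is always the difference T₁ − T₂ with
traction-free lateral faces.

### Closed-form stress and its oracle

The virgin engineering stress is σ(λ) = Ψ(λ)·(λ − λ⁻²) with
Ψ = (1 − f)·ℵ + (2f/3)(A₁ + (2A₂/3)(I₁ − 3)). The response function is
implemented as the *exact* chain-rule derivative of the Puso-consistent
energy:

ℵ = µ/(3Nλ_r) · [N(β + β′(λ_r − L(β))) − β′/β − 1/λ_r],

where L is the forward Langevin function and β′ = dβ/dλ_r =
3(1 + 2λ_r³)/(1 − λ_r³)². The classical textbook form drops the
β′(λ_r − L(β)) term because it vanishes for the exact inverse Langevin;
with the Puso approximation it contributes a few parts in 10⁴, and keeping
it makes σ agree with the central-difference derivative of W_T to machine
precision (the numeric derivative is the package's authoritative oracle;
`numeric_stress_oracle` uses h = 1e−5, falling back to a one-sided
difference at the λ ≤ 1 + h boundary).

### Mullins softening with residual strains

Unloading/reloading below the historical maximum stretch follows

τ₁ − τ₂ = {Ψ(λ² − λ⁻¹) + µλ₂²C(λ₁g₁ − λ₂g₂)} · e^(−b√(M−m)) · √(m/M),

with m = √(λ⁴ + 2λ⁻²), M = m(λ_max), and residual-strain terms
g_k = −4λ_k(λ_max,kⁿ − λ_k²) (the partial derivative of
Φ = Σ_a(λ_max,aⁿ − λ_a²)² with respect to λ_k, validated against finite
differences of Φ). M is defined as m evaluated at λ_max, which guarantees
m = M — and a softening factor of exactly 1 — at the reversal point. The
exponent n is fixed at 1 by default.

**Known limitation (reversal discontinuity).** With n = 1 the residual
term does not vanish at λ = λ_max, so the softened stress exceeds the
virgin stress by ~1% (≈1.7 kPa at λ_max = 1.3 for the liver constants) in
a sliver of width ~6×10⁻⁶ in λ just below the reversal point; the
square-root cusp of the exponential factor pulls it back below the virgin
curve immediately. The softened branch is therefore defined to apply
*strictly below* the historical maximum — the simulator's branch selection
uses the virgin table at or above it — and the dominance property
(softened ≤ virgin) is checked on [1, λ_max − 10⁻⁴], with the
reversal-point gap computed and reported separately rather than hidden.
With n = 2 the term would vanish at reversal, but n = 1 is the stated
default of the model and is kept.

The residual stretch λ_res (positive unloading strain) is the zero of the
softened stress, found by bisection; for the liver constants at
λ_max = 1.3 it is ≈ 1.0469.

## Equivalent-energy stiffness tables

The hybrid step equates the energy density of a one-dimensional spring,
W_s = k_s·λ(λ − 1)/(2ν_ij), with the tissue energy at the same stretch,
giving k_s(λ) = 2ν_ij·W_T(λ)/(λ² − λ). Tables are dense arrays on
λ ∈ [1 + 10⁻⁶, λ_max] with spacing dl = 10⁻³ (default), precomputed once
at initialization and never rebuilt in the simulation loop. The λ → 1
limit is the analytic value 0 (W_T is O((λ−1)²)); the force path
interpolates to exactly 0 at λ = 1 so a rest-length element exerts no
force. The denominator is computed as λ(λ−1) so the energy identity
k_s·λ(λ−1)/(2ν_ij) = W_T holds to float rounding at every node.
Stresses are kPa in the constitutive layer and converted to SI at the
table boundary, so k_s is in newtons and F = k_s·λ is a force.

The unloading branch needs a softened energy that the constitutive model
does not define in closed form; it is taken as the work integral of the
softened engineering stress from λ_res upward (energy = work along the
path, consistent with the energy-matching construction), clamped to 0
below λ_res so stiffness stays non-negative. The integral is accumulated
by trapezoid on a refined grid — dl/16 plus a geometrically graded tail
into the reversal point, where the softening factor's √(M−m) cusp defeats
a uniform grid — and agrees with adaptive quadrature to ≤10⁻⁵ relative.
One unloading table is built per distinct reversal stretch actually
reached, cached with the historical maximum quantized upward to 10⁻³ so an
element never uses a table whose reversal stretch is below its own
recorded maximum.

## Spring-mass simulation

Each unique mesh edge (from OBJ triangles or legacy-ASCII VTK triangles /
tetrahedra) is an element with rest length from the initial geometry.
Forces act along the element axis with magnitude, per the default
*energy-consistent* convention, F = k_s(λ_s)·λ_s — the form under which
the stored energy identity is exact. The classic Hooke-style form
F = k_s·(λ_s − 1) is available behind `force_convention="hooke-extension"`
for comparison; the two differ by a factor λ/(λ−1) and only the former
reproduces the table energies. Note F = k_s·λ is a *secant* force: it is
not the derivative of W_T·ν_ij·L, so energy bookkeeping for conservation
tests uses the work integral of the force law itself
(`spring_potential`).

Choices the model itself does not fix, made here as package defaults:

- Integrator: semi-implicit Euler (default) or velocity Verlet, dt default
  10⁻³ s, with `suggest_dt` providing a stability heuristic
  dt = 0.2·2/ω_max, ω_max = √(k_max/m_min), k_max from the steepest table
  tangent over the shortest rest length.
- Damping: simple velocity damping (coefficient in 1/s); zero preserves
  energy under Verlet to <1% over 10⁴ steps on the two-element fixture.
- Compression (λ < 1) is outside the model's claims; the response is
  linearized with the small-strain tangent extrapolated from the first
  table nodes (prevents unphysical zero resistance) and flagged in logs.
- Mass lumping: total mesh mass distributed per node proportional to
  incident element rest length; density default 1060 kg/m³ where a volume
  is defined (ellipsoid generator), otherwise an explicit total mass.
- Mullins history: per-element maximum stretch, non-decreasing, quantized
  to 10⁻³ for table caching.

### Virtual uniaxial tests

A quasi-static test is a sequence of equilibria: the driven face is
ramped 1 → λ_target → 1 in increments, and each increment's equilibrium of
the free nodes is found by a Newton-type root solve on the nodal forces
(warm-started with an affine predictor), with Mullins history updated from
converged stretches only. A damped dynamic-relaxation path
(`solver="dynamic"`, with an online kinetic-energy-versus-stored-energy
check) exercises the same time stepper the real-time loop uses. Reaction
force over the driven face divided by (number of driven nodes)·ν_ij is the
engineering stress.

The beam-level consistency check uses an axis-aligned-element beam
(`gen_beam_mesh(..., diagonals=False)`): without diagonals a uniaxial
stretch of the lattice has an exactly affine equilibrium, every axial
element sits at the applied stretch, and the boundary stress must equal
the single-spring secant prediction 2W_T(λ)/(λ−1) — isolating the element
law from homogenization effects. With face diagonals (the default mesh)
the lattice's effective axial response deliberately includes diagonal
contributions and is *not* expected to match the single-spring curve.

## Synthetic data

The generator emulates cyclic quasi-static uniaxial tension tests: three
cycles to increasing reversal stretches (1.15, 1.23, 1.30 — the canonical
protocol), loading by the virgin law above the previous cycle's maximum
and by the softened law below it (the standard Mullins idealization for
reloading), unloading down to the residual stretch where the stress
crosses zero. Noise is i.i.d. multiplicative lognormal with mean 1 and
configurable coefficient of variation (default 2%, a realistic load-cell /
specimen variability scale for soft-tissue testing); additive Gaussian
noise scaled to the RMS clean stress is available behind a flag. Curves
are bit-reproducible for a fixed seed.

What the generator does **not** emulate: machine compliance, grip
slippage, preconditioning drift, viscoelastic rate effects, and
specimen-to-specimen heterogeneity. Passing recovery tests on these data
therefore demonstrates correctness of the estimation machinery on the
model class, not robustness to real experimental artefacts.

## Parameter estimation

Bounded least squares on engineering stress, pooled over all branches
(the model's own source states no objective; plain LSQ is the default and
a relative-error loss is available behind a flag), using trust-region
reflective with bounds µ ∈ (10⁻⁴, 10³) kPa, N ∈ (1.01, 100) (lower bound
raised to I₁(λ_top)/3 so the lock stretch stays above the data),
b ∈ [0, 100], A₁, A₂, C ∈ [0, 10⁶] kPa, f ∈ [0, 1], n fixed at 1.
Twenty multi-starts (default) from a seeded Latin hypercube over
log-scaled bounds (linear for f); deterministic given the seed.

**Identifiability.** In uniaxial data f enters only through (1−f)µ, f·A₁
and f·A₂, and C only through µ·C, so individual values of µ, f, A₁, A₂, C
trade off along flat directions (and µ–N retain a softer trade-off at
finite strain). Fits are therefore validated *predictively*: the fitted
model's stress curves must reproduce the generating model's (noiseless
data: to ~10⁻⁴ of the curve scale; 2% noise: well within 5%). Individual
parameter values returned by the optimizer are not claimed to be unique.
Reported R² is 1 − SS_res/SS_tot per branch and may be negative for fits
worse than the mean predictor.

## Problem sizes and numerical defaults

Default table spacing dl = 10⁻³ (grid convergence: halving dl moves
interpolated stiffness by <1%); derivative oracle on 200 points of
[1.01, 1.29]; Langevin round-trip on 400 points of [0, 0.95] (measured
Puso error ≈3.4%, documented bound 5%); recovery fits on 3 cycles × 67
points per branch; beam tests on a 3×1×1 diagonal-free lattice; the
scaled demonstration steps a subdivision-4 icosahedral ellipsoid (2562
nodes, 7680 elements) for 100 steps under gravity, logging wall-clock
frame times without asserting any frame rate (hardware-dependent).
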