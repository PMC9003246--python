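"""Non-Gaussian hyperelastic constitutive law with Mullins-type stress softening.

The material is modelled as a rule-of-mixtures composite: an isotropic
matrix described by eight-chain (inverse-Langevin) non-Gaussian statistics,
plus an "isotropized" anisotropic fibre contribution carried by two
polynomial invariant terms.  The total strain energy density is

    W_T = (1 - f) * W_iso + f * W_aniso

with ``f`` the anisotropic volume fraction.  Stress softening and residual
strains on unloading (the Mullins effect) are modelled by scaling the
virgin stress difference with ``exp(-b*sqrt(M - m)) * sqrt(m/M)`` and adding
a residual-strain term controlled by ``C``.

Only incompressible uniaxial kinematics are supported: the principal
stretches are (lam, lam**-0.5, lam**-0.5) and hydrostatic pressure is
eliminated by forming stress differences with traction-free lateral faces.

Units: stresses and energy densities in kPa, stretches dimensionless.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DomainError",
    "MaterialParams",
    "UniaxialState",
    "StressPoint",
    "LIVER_PARAMS",
    "puso_inverse_langevin",
    "langevin",
    "uniaxial_state",
    "w_iso",
    "w_aniso",
    "w_total",
    "response_fn",
    "virgin_stress",
    "virgin_stress_vec",
    "softened_stress_vec",
    "softening_variables",
    "softening_factor",
    "residual_term_g",
    "softened_stress",
    "residual_stretch",
    "numeric_stress_oracle",
    "LAM_R_GUARD",
]

# Relative chain stretches at or above this value are treated as fully
# extended (lock stretch): operations raise instead of returning inf.
LAM_R_GUARD = 0.999999

# Below this |beta| the Langevin function uses its Taylor series
# beta/3 - beta**3/45 (the direct coth formula loses precision).
_LANGEVIN_SERIES_THRESHOLD = 1e-4


class DomainError(ValueError):
    """A kinematic or material quantity left its admissible domain."""


# ---------------------------------------------------------------------------
# Parameters and state containers
# ---------------------------------------------------------------------------

_JSON_KEYS = ("mu_kPa", "N", "b", "A1_kPa", "A2_kPa", "C_kPa", "f", "n")


@dataclass(frozen=True)
class MaterialParams:
    """Constants of the mixed non-Gaussian / isotropized-anisotropic model.

    Parameters
    ----------
    mu : float
        Shear-modulus-like parameter of the non-Gaussian matrix term (kPa).
    N : float
        Number of chain links; the lock stretch is ``sqrt(N)``. Must exceed 1.
    b : float
        Dimensionless softening exponent (>= 0).
    A1, A2 : float
        Anisotropic energy parameters (kPa).
    C : float
        Residual-strain parameter (kPa).
    f : float
        Anisotropic volume fraction in [0, 1].
    n : float
        Residual-strain fitting exponent (default 1).
    """

    mu: float
    N: float
    b: float = 0.0
    A1: float = 0.0
    A2: float = 0.0
    C: float = 0.0
    f: float = 0.0
    n: float = 1.0

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if not self.N > 1:
            raise ValueError(f"N must be > 1 (lock stretch sqrt(N)), got {self.N}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        if self.b < 0:
            raise ValueError(f"b must be >= 0, got {self.b}")

    @property
    def lock_stretch(self) -> float:
        """Fully-extended chain stretch ``sqrt(N)``."""
        return math.sqrt(self.N)

    def to_dict(self) -> dict:
        return {
            "mu_kPa": self.mu,
            "N": self.N,
            "b": self.b,
            "A1_kPa": self.A1,
            "A2_kPa": self.A2,
            "C_kPa": self.C,
            "f": self.f,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialParams":
        missing = [k for k in _JSON_KEYS if k not in d]
        if missing:
            raise ValueError(f"material parameter file missing keys: {missing}")
        return cls(
            mu=d["mu_kPa"], N=d["N"], b=d["b"], A1=d["A1_kPa"],
            A2=d["A2_kPa"], C=d["C_kPa"], f=d["f"], n=d["n"],
        )

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "MaterialParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def fingerprint(self) -> str:
        """Short stable hash of the parameter values, for table sidecars."""
        import hashlib

        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


#: Porcine-liver parenchyma constants obtained from cyclic uniaxial tests.
LIVER_PARAMS = MaterialParams(
    mu=0.1, N=1.1974, b=3.3389, A1=9.6754, A2=7543.6, C=9.5273, f=0.2755, n=1.0
)


@dataclass(frozen=True)
class UniaxialState:
    """Kinematic quantities of an incompressible simple-extension state."""

    lam: float
    lam2: float
    I1: float
    I3: float
    lam_chain: float
    lam_r: float
    m: float
    M: float


@dataclass(frozen=True)
class StressPoint:
    """One engineering stress sample on the virgin or softened branch."""

    lam: float
    sigma: float  # kPa
    branch: str  # "virgin" | "softened"
    lam_max: float | None = None

    def __post_init__(self) -> None:
        if self.branch not in ("virgin", "softened"):
            raise ValueError(f"unknown branch {self.branch!r}")
        if self.branch == "softened":
            if self.lam_max is None:
                raise ValueError("softened branch requires lam_max")
            if not (1.0 <= self.lam <= self.lam_max + 1e-12):
                raise ValueError(
                    f"softened branch requires 1 <= lam <= lam_max, "
                    f"got lam={self.lam}, lam_max={self.lam_max}"
                )


# ---------------------------------------------------------------------------
# Langevin statistics
# ---------------------------------------------------------------------------

def puso_inverse_langevin(lam_r):
    """Puso Pade approximation of the inverse Langevin function.

    ``beta = 3*lam_r / (1 - lam_r**3)``; diverges as lam_r -> 1.
    """
    lam_r = np.asarray(lam_r, dtype=float)
    if np.any(lam_r < 0) or np.any(lam_r >= 1):
        bad = lam_r[(lam_r < 0) | (lam_r >= 1)]
        raise DomainError(
            f"relative chain stretch must lie in [0, 1), got {np.atleast_1d(bad)[0]}"
        )
    out = 3.0 * lam_r / (1.0 - lam_r**3)
    return out.item() if out.ndim == 0 else out


def _dbeta_dlamr(lam_r):
    """Derivative of the Puso approximation with respect to lam_r."""
    lam_r = np.asarray(lam_r, dtype=float)
    return 3.0 * (1.0 + 2.0 * lam_r**3) / (1.0 - lam_r**3) ** 2


def langevin(beta):
    """Langevin function ``L(beta) = coth(beta) - 1/beta``.

    The removable singularity at 0 is handled with the series
    ``beta/3 - beta**3/45`` below a small threshold; saturates to 1.
    """
    beta = np.asarray(beta, dtype=float)
    small = np.abs(beta) < _LANGEVIN_SERIES_THRESHOLD
    b_safe = np.where(small, 1.0, beta)
    # 1/tanh overflows for huge beta only through exp; clip the argument
    b_clip = np.clip(b_safe, -700.0, 700.0)
    with np.errstate(over="ignore"):
        direct = 1.0 / np.tanh(b_clip) - 1.0 / b_safe
    series = beta / 3.0 - beta**3 / 45.0
    out = np.where(small, series, direct)
    return out.item() if out.ndim == 0 else out


def inverse_langevin_exact(lam_r, tol: float = 1e-14):
    """Exact inverse Langevin via Newton iteration (independent oracle).

    Kept deliberately separate from :func:`puso_inverse_langevin`; used to
    measure the approximation's error, never inside the constitutive law.
    """
    lam_r = np.atleast_1d(np.asarray(lam_r, dtype=float))
    if np.any(lam_r < 0) or np.any(lam_r >= 1):
        raise DomainError("lam_r must lie in [0, 1) for exact inversion")
    beta = puso_inverse_langevin(lam_r)  # good starting point
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    beta[beta == 0.0] = 1e-12
    for _ in range(100):
        f = langevin(beta) - lam_r
        # L'(beta) = 1/beta^2 - csch^2(beta)
        with np.errstate(over="ignore"):
            sinh = np.sinh(np.clip(beta, -700, 700))
        df = 1.0 / beta**2 - 1.0 / sinh**2
        step = f / df
        beta = beta - step
        if np.max(np.abs(step)) < tol * np.maximum(1.0, np.max(np.abs(beta))):
            break
    return beta if beta.size > 1 else beta.item()


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def uniaxial_state(lam, params: MaterialParams, lam_max: float | None = None) -> UniaxialState:
    """Build the full kinematic state of incompressible simple extension.

    lam2 = lam3 = lam**-1/2, so I3 = 1 identically.  ``lam_max`` (the
    historical maximum stretch) defaults to ``lam`` itself, which makes the
    state lie on the virgin path (m = M).
    """
    lam = float(lam)
    if lam <= 0:
        raise DomainError(f"stretch must be positive, got {lam}")
    if lam_max is None:
        lam_max = lam
    lam2 = lam ** -0.5
    I1 = lam**2 + 2.0 / lam
    I3 = (lam * lam2 * lam2) ** 2
    lam_chain = math.sqrt(I1 / 3.0)
    lam_r = lam_chain / math.sqrt(params.N)
    if lam_r >= LAM_R_GUARD:
        raise DomainError(
            f"relative chain stretch {lam_r:.8f} at lam={lam} reaches the "
            f"lock stretch sqrt(N)={params.lock_stretch:.6f}"
        )
    m, M = softening_variables(min(lam, lam_max), lam_max)
    return UniaxialState(
        lam=lam, lam2=lam2, I1=I1, I3=I3,
        lam_chain=lam_chain, lam_r=lam_r, m=m, M=M,
    )


# ---------------------------------------------------------------------------
# Strain energy densities
# ---------------------------------------------------------------------------

def _log_beta_over_sinh(beta):
    """Numerically stable ``log(beta / sinh(beta))`` for beta > 0."""
    beta = np.asarray(beta, dtype=float)
    small = beta < 20.0
    b_small = np.where(small, beta, 1.0)
    direct = np.log(b_small / np.sinh(b_small))
    # log(sinh b) = b - log 2 + log1p(-exp(-2b))
    stable = np.log(beta) - (beta - math.log(2.0) + np.log1p(-np.exp(-2.0 * beta)))
    out = np.where(small, direct, stable)
    return out.item() if out.ndim == 0 else out


def _w_iso_raw(lam_r, params: MaterialParams):
    """Bracketed mu-term of the non-Gaussian energy, before normalization."""
    beta = puso_inverse_langevin(lam_r)
    return params.mu * (
        params.N * (beta * lam_r + _log_beta_over_sinh(beta))
        - np.log(beta * lam_r)
    )


def w_iso(state: UniaxialState, params: MaterialParams) -> float:
    """Isotropic (matrix) non-Gaussian strain energy density, kPa.

    The integration constant is chosen so the energy vanishes in the
    undeformed state (lam = 1, where lam_r = 1/sqrt(N)).
    """
    if state.lam_r >= LAM_R_GUARD:
        raise DomainError(f"chain fully extended: lam_r={state.lam_r}")
    c = -_w_iso_raw(1.0 / math.sqrt(params.N), params)
    return float(_w_iso_raw(state.lam_r, params) + c)


def w_aniso(state: UniaxialState, params: MaterialParams) -> float:
    """Isotropized anisotropic (fibre) energy density, kPa.

    ``(A1/3)(I1-3) + (A2/9)(I1-3)^2 - (2A1/3) ln sqrt(I3)``; the log term
    vanishes under incompressibility (I3 = 1) but is kept for clarity.
    """
    d = state.I1 - 3.0
    return float(
        params.A1 / 3.0 * d
        + params.A2 / 9.0 * d * d
        - 2.0 * params.A1 / 3.0 * math.log(math.sqrt(state.I3))
    )


def w_total(state: UniaxialState, params: MaterialParams) -> float:
    """Mixture energy density ``(1-f) w_iso + f w_aniso`` (kPa)."""
    f = params.f
    wi = w_iso(state, params) if f < 1.0 else 0.0
    wa = w_aniso(state, params) if f > 0.0 else 0.0
    return (1.0 - f) * wi + f * wa


def w_total_at(lam, params: MaterialParams) -> float:
    """Convenience: total energy density at axial stretch ``lam``."""
    return w_total(uniaxial_state(lam, params), params)


# ---------------------------------------------------------------------------
# Stress laws
# ---------------------------------------------------------------------------

def response_fn(state: UniaxialState, params: MaterialParams) -> float:
    """Non-Gaussian response function (kPa).

    Defined so that the isotropic contribution to the Cauchy stress
    difference is ``(1-f) * aleph * (lam1^2 - lam2^2)``.  Computed as the
    exact chain-rule derivative of the Puso-consistent energy,

        aleph = mu / (3 N lam_r)
                * [N (beta + beta' (lam_r - L(beta))) - beta'/beta - 1/lam_r].

    The classical textbook form drops the ``beta' (lam_r - L(beta))``
    correction because it vanishes for the exact inverse Langevin; with the
    Puso approximation it contributes a few parts in 1e4 and keeping it
    makes the closed-form stress agree with the numeric derivative of the
    energy to machine precision.
    """
    return float(_aleph_vec(state.lam_r, params))


def _aleph_vec(lam_r, params: MaterialParams):
    """Vectorized response function; lam_r may be an array."""
    lam_r = np.asarray(lam_r, dtype=float)
    if np.any(lam_r >= LAM_R_GUARD):
        raise DomainError(
            f"chain fully extended: lam_r={float(np.max(lam_r)):.8f}"
        )
    beta = puso_inverse_langevin(lam_r)
    dbeta = _dbeta_dlamr(lam_r)
    out = (
        params.mu / (3.0 * params.N * lam_r)
        * (
            params.N * (beta + dbeta * (lam_r - langevin(beta)))
            - dbeta / beta
            - 1.0 / lam_r
        )
    )
    return out.item() if out.ndim == 0 else out


def _lam_r_vec(lam, params: MaterialParams):
    lam = np.asarray(lam, dtype=float)
    I1 = lam**2 + 2.0 / lam
    return np.sqrt(I1 / (3.0 * params.N))


def _psi_vec(lam, params: MaterialParams):
    """Stress-difference prefactor (1-f) aleph + fibre term, vectorized."""
    lam = np.asarray(lam, dtype=float)
    I1 = lam**2 + 2.0 / lam
    aniso = 2.0 * params.f / 3.0 * (
        params.A1 + 2.0 * params.A2 / 3.0 * (I1 - 3.0)
    )
    if params.f < 1.0:
        iso = (1.0 - params.f) * _aleph_vec(_lam_r_vec(lam, params), params)
    else:
        iso = 0.0
    return iso + aniso


def virgin_stress_vec(lam, params: MaterialParams):
    """Virgin engineering stress (kPa) at an array of stretches >= 1."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 1.0 - 1e-12):
        raise DomainError("virgin stress defined for lam >= 1")
    lam = np.maximum(lam, 1.0)
    return _psi_vec(lam, params) * (lam - lam**-2)


def softened_stress_vec(lam, lam_max, params: MaterialParams):
    """Softened engineering stress (kPa) at an array of stretches in [1, lam_max]."""
    lam = np.asarray(lam, dtype=float)
    lam_max = float(lam_max)
    if np.any(lam < 1.0 - 1e-12) or np.any(lam > lam_max + 1e-12):
        raise DomainError("softened branch requires 1 <= lam <= lam_max")
    lam = np.clip(lam, 1.0, lam_max)
    lam2 = lam**-0.5
    m = np.sqrt(lam**4 + 2.0 / lam**2)
    M = math.sqrt(lam_max**4 + 2.0 / lam_max**2)
    factor = np.exp(-params.b * np.sqrt(np.maximum(M - m, 0.0))) * np.sqrt(m / M)
    lmax2 = lam_max**-0.5
    n = params.n
    g1 = -4.0 * lam * (lam_max**n - lam**2)
    g2 = -4.0 * lam2 * (lmax2**n - lam2**2)
    bracket = (
        _psi_vec(lam, params) * (lam**2 - 1.0 / lam)
        + params.mu * lam2**2 * params.C * (lam * g1 - lam2 * g2)
    )
    return bracket * factor / lam


def virgin_stress(lam, params: MaterialParams) -> StressPoint:
    """Engineering stress on the primary (virgin) loading path.

    From the Cauchy stress difference T1 - T2 with traction-free lateral
    faces (which eliminates the hydrostatic pressure) divided by lam:
    ``sigma = psi(lam) * (lam - lam**-2)``.  Identical to d(W_T)/dlam.
    """
    lam = float(lam)
    if lam < 1.0 - 1e-12:
        raise DomainError(f"virgin stress defined for lam >= 1, got {lam}")
    lam = max(lam, 1.0)
    uniaxial_state(lam, params)  # domain guard (lock stretch)
    sigma = virgin_stress_vec(lam, params)
    return StressPoint(lam=lam, sigma=float(sigma), branch="virgin")


def softening_variables(lam, lam_max):
    """Mullins softening variables ``m = sqrt(lam^4 + 2 lam^-2)``, M = m(lam_max)."""
    lam = float(lam)
    lam_max = float(lam_max)
    if lam < 1.0 - 1e-12:
        raise DomainError(f"lam must be >= 1, got {lam}")
    if lam > lam_max + 1e-12:
        raise DomainError(f"lam={lam} exceeds lam_max={lam_max}")
    m = math.sqrt(lam**4 + 2.0 / lam**2)
    M = math.sqrt(lam_max**4 + 2.0 / lam_max**2)
    return m, M


def softening_factor(m, M, b):
    """Stress-softening multiplier ``exp(-b sqrt(M - m)) sqrt(m/M)`` in (0, 1]."""
    if m > M + 1e-12:
        raise DomainError(f"m={m} exceeds M={M}")
    if m <= 0:
        raise DomainError(f"m must be positive, got {m}")
    gap = max(M - m, 0.0)
    return math.exp(-b * math.sqrt(gap)) * math.sqrt(m / M)


def residual_term_g(lam, lam_max, n=1.0):
    """Residual-strain derivative terms g_k = dPhi/dlam_k for uniaxial kinematics.

    Phi = sum_a (lam_max_a^n - lam_a^2)^2 with lam_max_a the principal
    stretches at the reversal point; g_k = -4 lam_k (lam_max_k^n - lam_k^2).
    Returns (g1, g2, g3); g2 == g3 by symmetry.
    """
    lam = float(lam)
    lam_max = float(lam_max)
    lams = (lam, lam**-0.5, lam**-0.5)
    lmaxs = (lam_max, lam_max**-0.5, lam_max**-0.5)
    return tuple(-4.0 * lk * (lmk**n - lk**2) for lk, lmk in zip(lams, lmaxs))


def softened_stress(lam, lam_max, params: MaterialParams) -> StressPoint:
    """Engineering stress on the unloading/reloading (softened) path.

    The virgin stress difference plus the residual-strain term
    ``mu * lam2^2 * C * (lam1 g1 - lam2 g2)`` is scaled by the softening
    factor and converted to engineering stress by dividing by lam.

    Note: with n = 1 the residual term does not vanish at the reversal
    point, so the softened stress slightly exceeds the virgin stress in a
    very narrow band (width ~1e-5 in lam for the liver constants) just
    below lam_max.  The branch is meant to be used strictly below the
    historical maximum stretch; see the methods documentation.
    """
    lam = float(lam)
    lam_max = float(lam_max)
    if not (1.0 - 1e-12 <= lam <= lam_max + 1e-12):
        raise DomainError(
            f"softened branch requires 1 <= lam <= lam_max, got "
            f"lam={lam}, lam_max={lam_max}"
        )
    lam = min(max(lam, 1.0), lam_max)
    uniaxial_state(lam, params, lam_max=lam_max)  # domain guard
    sigma = softened_stress_vec(lam, lam_max, params)
    return StressPoint(lam=lam, sigma=float(sigma), branch="softened", lam_max=lam_max)


def residual_stretch(params: MaterialParams, lam_max) -> float:
    """Residual stretch: the zero-stress crossing of the softened branch.

    Returns the lam in (1, lam_max) where the softened engineering stress
    vanishes, or 1.0 if the stress is non-negative on the whole branch
    (no residual strain, e.g. C = 0).
    """
    lam_max = float(lam_max)

    def s(lam):
        return softened_stress(lam, lam_max, params).sigma

    lo = 1.0
    if s(lo) >= 0.0:
        return 1.0
    hi = lam_max
    if s(hi) <= 0.0:
        raise DomainError(
            f"softened stress non-positive on the whole branch up to {lam_max}"
        )
    return float(brentq(s, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# Independent numeric oracle
# ---------------------------------------------------------------------------

def numeric_stress_oracle(lam, params: MaterialParams, h: float = 1e-5) -> float:
    """Central-difference derivative of the total energy density (kPa).

    ``[W_T(lam+h) - W_T(lam-h)] / (2h)`` on the incompressible uniaxial
    energy — the authoritative check for the closed-form virgin stress.
    Requires ``lam > 1 + h`` so the stencil stays inside the branch; at or
    below that boundary a one-sided forward difference of order h is used.
    """
    lam = float(lam)
    if lam < 1.0:
        raise DomainError(f"oracle defined for lam >= 1, got {lam}")
    if lam > 1.0 + h:
        return (w_total_at(lam + h, params) - w_total_at(lam - h, params)) / (2.0 * h)
    return (w_total_at(lam + h, params) - w_total_at(lam, params)) / h
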