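"""Unit and property tests for the constitutive layer.

Closed-form stresses are always checked against independent oracles:
central differences of the energy, Newton inversion of the exact Langevin
function, and frozen arbitrary-precision evaluations of the energy
densities.
"""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eesm import (
    DomainError,
    MaterialParams,
    inverse_langevin_exact,
    langevin,
    numeric_stress_oracle,
    puso_inverse_langevin,
    residual_stretch,
    residual_term_g,
    response_fn,
    softened_stress,
    softening_factor,
    softening_variables,
    uniaxial_state,
    virgin_stress,
    w_aniso,
    w_iso,
    w_total,
    w_total_at,
)

# frozen with 50-digit arbitrary-precision arithmetic
W_ISO_1p2 = 0.0022444296421180182  # mu=0.1, N=1.1974, lam=1.2
W_ANISO_1p3 = 44.48523525443787  # A1=9.6754, A2=7543.6, lam=1.3


class TestLangevin:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.0, 0.0), (0.5, 1.714286), (0.9, 9.963100)],
    )
    def test_puso_values(self, x, expected):
        assert puso_inverse_langevin(x) == pytest.approx(expected, abs=5e-7)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_puso_domain(self, bad):
        with pytest.raises(DomainError, match=str(bad)):
            puso_inverse_langevin(bad)

    def test_puso_monotone(self):
        xs = np.linspace(0, 0.99, 500)
        assert np.all(np.diff(puso_inverse_langevin(xs)) > 0)

    def test_langevin_limits(self):
        assert langevin(0.0) == 0.0
        assert abs(langevin(1e6) - 1.0) <= 1.01e-6  # saturation: 1 - 1/beta

    def test_langevin_series_matches_direct_near_threshold(self):
        """Around the series switch-over both evaluation paths agree (the
        Taylor error ~beta^5 and the cancellation error are both tiny)."""
        betas = np.linspace(5e-5, 2e-4, 101)  # straddles the 1e-4 threshold
        series = betas / 3.0 - betas**3 / 45.0
        assert np.max(np.abs(langevin(betas) - series)) < 1e-10

    def test_roundtrip_against_newton_oracle(self):
        """Puso error vs the exact inverse stays below the documented bound."""
        xs = np.linspace(1e-6, 0.95, 300)
        beta_exact = inverse_langevin_exact(xs)
        assert np.max(np.abs(langevin(beta_exact) - xs)) < 1e-10  # oracle closes
        err = np.abs(langevin(np.asarray(puso_inverse_langevin(xs))) - xs) / xs
        assert err.max() < 0.05  # measured max ~= 3.4e-2
        assert err.max() > 0.01  # the approximation genuinely differs


class TestKinematics:
    @given(lam=st.floats(1.0, 1.32))
    @settings(max_examples=50, derandomize=True)
    def test_incompressibility(self, lam):
        s = uniaxial_state(lam, MaterialParams(mu=0.1, N=1.1974))
        assert abs(s.I3 - 1.0) < 1e-12
        assert 0.0 <= s.lam_r < 1.0

    def test_rest_state(self, liver):
        s = uniaxial_state(1.0, liver)
        assert s.I1 == pytest.approx(3.0, abs=1e-14)
        assert s.lam_chain == pytest.approx(1.0, abs=1e-14)
        assert s.m == pytest.approx(math.sqrt(3.0), abs=1e-12)

    def test_lock_stretch_guard(self, liver):
        # chain lock sqrt(N) = 1.0942 corresponds to axial stretch ~1.507
        with pytest.raises(DomainError, match="lock"):
            uniaxial_state(1.6, liver)


class TestEnergies:
    def test_zero_at_rest(self, liver):
        s = uniaxial_state(1.0, liver)
        assert w_iso(s, liver) == pytest.approx(0.0, abs=1e-15)
        assert w_aniso(s, liver) == pytest.approx(0.0, abs=1e-15)
        assert w_total(s, liver) == pytest.approx(0.0, abs=1e-15)

    def test_w_iso_frozen_oracle(self, iso_only):
        s = uniaxial_state(1.2, iso_only)
        assert w_iso(s, iso_only) == pytest.approx(W_ISO_1p2, rel=1e-12)

    def test_w_iso_derivative(self, iso_only):
        h = 1e-6
        num = (
            w_iso(uniaxial_state(1.1 + h, iso_only), iso_only)
            - w_iso(uniaxial_state(1.1 - h, iso_only), iso_only)
        ) / (2 * h)
        sigma = virgin_stress(1.1, iso_only).sigma  # f=0: sigma = dW_iso/dlam
        assert sigma == pytest.approx(num, rel=1e-6)

    def test_w_aniso_frozen_oracle(self, liver):
        s = uniaxial_state(1.3, liver)
        assert w_aniso(s, liver) == pytest.approx(W_ANISO_1p3, rel=1e-12)

    def test_w_aniso_quadratic_growth(self, liver):
        # log-log slope of the A2-dominated regime tends to 2
        lams = np.linspace(1.25, 1.31, 20)
        d = np.array([uniaxial_state(l, liver).I1 - 3 for l in lams])
        w = np.array([w_aniso(uniaxial_state(l, liver), liver) for l in lams])
        slope = np.polyfit(np.log(d), np.log(w), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_mixture_degeneracy(self, liver):
        lone_iso = MaterialParams(mu=0.1, N=1.1974, A1=9.6754, A2=7543.6, f=0.0)
        lone_aniso = MaterialParams(mu=0.1, N=1.1974, A1=9.6754, A2=7543.6, f=1.0)
        s = uniaxial_state(1.2, lone_iso)
        assert w_total(s, lone_iso) == w_iso(s, lone_iso)
        assert w_total(s, lone_aniso) == w_aniso(s, lone_aniso)

    def test_mixture_weights(self, liver):
        s = uniaxial_state(1.3, liver)
        expected = (1 - liver.f) * w_iso(s, liver) + liver.f * w_aniso(s, liver)
        assert w_total(s, liver) == pytest.approx(expected, rel=1e-15)

    def test_monotone_in_stretch(self, liver):
        lams = np.linspace(1.0, 1.3, 200)
        w = np.array([w_total_at(l, liver) for l in lams])
        assert np.all(np.diff(w) > 0)


class TestVirginStress:
    def test_zero_at_rest(self, liver):
        assert virgin_stress(1.0, liver).sigma == 0.0

    def test_energy_derivative_oracle(self, liver, lam_grid):
        """The defining contract: closed form == dW_T/dlam to <= 1e-3."""
        for lam in lam_grid:
            sigma = virgin_stress(lam, liver).sigma
            oracle = numeric_stress_oracle(lam, liver)
            assert sigma == pytest.approx(oracle, rel=1e-3)

    def test_strictly_increasing(self, liver):
        lams = np.linspace(1.0, 1.3, 200)
        sig = np.array([virgin_stress(l, liver).sigma for l in lams])
        assert np.all(np.diff(sig) > 0)

    def test_response_fn_finite_at_rest(self, liver):
        aleph = response_fn(uniaxial_state(1.0 + 1e-9, liver), liver)
        assert np.isfinite(aleph) and aleph > 0

    def test_response_fn_stiffening(self, liver):
        lams = np.linspace(1.2, 1.32, 30)  # approaching lock stretch
        al = [response_fn(uniaxial_state(l, liver), liver) for l in lams]
        assert np.all(np.diff(al) > 0)

    def test_domain_error(self, liver):
        with pytest.raises(DomainError):
            virgin_stress(0.8, liver)


class TestSoftening:
    def test_variables(self):
        m, M = softening_variables(1.0, 1.3)
        assert m == pytest.approx(math.sqrt(3.0), rel=1e-12)
        m, M = softening_variables(1.3, 1.3)
        assert m == M
        with pytest.raises(DomainError):
            softening_variables(1.4, 1.3)

    def test_m_monotone(self):
        lams = np.linspace(1.0, 1.3, 100)
        ms = [softening_variables(l, 1.3)[0] for l in lams]
        assert np.all(np.diff(ms) > 0)

    def test_factor_normalization(self):
        assert softening_factor(2.0, 2.0, 3.3389) == 1.0

    def test_factor_b_zero(self):
        m, M = 1.0, 4.0
        assert softening_factor(m, M, 0.0) == pytest.approx(0.5)  # sqrt(m/M)

    def test_factor_monotone(self):
        M = softening_variables(1.3, 1.3)[1]
        ms = np.linspace(math.sqrt(3), M, 100)
        fs = [softening_factor(m, M, 3.3389) for m in ms]
        assert np.all(np.diff(fs) >= 0)
        with pytest.raises(DomainError):
            softening_factor(M + 1, M, 1.0)

    @pytest.mark.parametrize(
        "n, lam, which_zero",
        [(1.0, None, "g1"), (2.0, 1.3, "all")],
    )
    def test_residual_g_roots(self, n, lam, which_zero):
        lam_max = 1.3
        if which_zero == "g1":
            g = residual_term_g(math.sqrt(lam_max), lam_max, n)
            assert g[0] == pytest.approx(0.0, abs=1e-12)
        else:
            g = residual_term_g(lam_max, lam_max, n)
            assert np.allclose(g, 0.0, atol=1e-12)

    def test_residual_g_finite_difference(self):
        """g_k must be the gradient of Phi = sum (lam_max_a^n - lam_a^2)^2."""
        lam, lam_max, n = 1.17, 1.3, 1.0
        lams = np.array([lam, lam**-0.5, lam**-0.5])
        lmaxs = np.array([lam_max, lam_max**-0.5, lam_max**-0.5])

        def phi(v):
            return np.sum((lmaxs**n - v**2) ** 2)

        g = residual_term_g(lam, lam_max, n)
        h = 1e-7
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            num = (phi(lams + e) - phi(lams - e)) / (2 * h)
            assert g[k] == pytest.approx(num, rel=1e-6)


class TestSoftenedStress:
    def test_inert_softening_matches_virgin(self):
        p = MaterialParams(mu=0.1, N=1.1974, b=0.0, A1=9.6754, A2=7543.6,
                           C=0.0, f=0.2755)
        lam = 1.3  # at reversal: m = M so even the sqrt(m/M) factor is 1
        assert softened_stress(lam, 1.3, p).sigma == pytest.approx(
            virgin_stress(lam, p).sigma, rel=1e-12
        )

    def test_residual_stretch_exists(self, liver):
        lam_res = residual_stretch(liver, 1.3)
        assert 1.0 < lam_res < 1.3
        assert softened_stress(lam_res, 1.3, liver).sigma == pytest.approx(0.0, abs=1e-9)

    def test_dominance_below_reversal(self, liver):
        """Softened <= virgin on the branch interior (used strictly below
        the historical maximum); the ~1e-5 sliver at the reversal point is
        excluded and its gap is checked separately."""
        lams = np.linspace(1.0, 1.3 - 1e-4, 400)
        for lam in lams:
            assert (
                softened_stress(lam, 1.3, liver).sigma
                <= virgin_stress(lam, liver).sigma + 1e-9
            )

    def test_reversal_gap_is_small_and_positive(self, liver):
        """With n = 1 the residual term leaves a small positive stress gap
        exactly at the reversal point (softened slightly above virgin)."""
        gap = (
            softened_stress(1.3, 1.3, liver).sigma
            - virgin_stress(1.3, liver).sigma
        )
        assert 0 < gap < 0.02 * virgin_stress(1.3, liver).sigma

    def test_domain(self, liver):
        with pytest.raises(DomainError):
            softened_stress(1.31, 1.3, liver)


class TestNumericOracle:
    def test_richardson_order(self, liver):
        """Central differences converge with order h^2."""
        lam, exact = 1.15, virgin_stress(1.15, liver).sigma
        e1 = abs(numeric_stress_oracle(lam, liver, h=1e-3) - exact)
        e2 = abs(numeric_stress_oracle(lam, liver, h=5e-4) - exact)
        assert e1 / e2 == pytest.approx(4.0, rel=0.3)

    def test_boundary_one_sided(self, liver):
        # at lam <= 1 + h the oracle falls back to a forward difference
        v = numeric_stress_oracle(1.0, liver, h=1e-5)
        assert np.isfinite(v)
        with pytest.raises(DomainError):
            numeric_stress_oracle(0.99, liver)


class TestMaterialParams:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(mu=-1, N=2), dict(mu=1, N=0.5), dict(mu=1, N=2, f=1.5),
         dict(mu=1, N=2, b=-1)],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            MaterialParams(**kwargs)

    def test_json_roundtrip_exact(self, liver, tmp_path):
        path = tmp_path / "liver.json"
        liver.to_json(path)
        again = MaterialParams.from_json(path)
        assert again == liver
        keys = set(json.loads(path.read_text()))
        assert keys == {"mu_kPa", "N", "b", "A1_kPa", "A2_kPa", "C_kPa", "f", "n"}

    @given(
        mu=st.floats(1e-3, 10), N=st.floats(1.2, 50),
        f=st.floats(0, 1), b=st.floats(0, 10),
    )
    @settings(max_examples=30, derandomize=True)
    def test_energy_normalization_property(self, mu, N, f, b):
        """W_total(lam=1) = 0 for any admissible parameter set."""
        p = MaterialParams(mu=mu, N=N, b=b, A1=1.0, A2=1.0, C=1.0, f=f)
        assert w_total_at(1.0, p) == pytest.approx(0.0, abs=1e-13)


def test_gaussian_limit_of_small_strain_modulus():
    """For N -> large the initial tangent modulus stabilizes at the
    Gaussian-chain limit of this energy.  With the -ln(beta*lam_r) chain
    term the limit of the uniaxial tangent modulus is mu (the per-chain
    log term cancels two thirds of the classical 3*mu)."""
    h = 1e-6
    moduli = []
    for N in (10.0, 100.0, 1000.0):
        p = MaterialParams(mu=0.1, N=N)
        moduli.append(virgin_stress(1.0 + h, p).sigma / h)
    assert abs(moduli[2] - 0.1) < abs(moduli[1] - 0.1) < abs(moduli[0] - 0.1)
    assert moduli[2] == pytest.approx(0.1, rel=0.01)
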