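"""Unit and oracle tests for the repression functions and model RHSs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

from circlock import models
from circlock.models import (
    CoreKaiParams,
    DomainError,
    KimForgerParams,
    NeurosporaParams,
    TTFLParams,
    effective_constants,
    free_kaiA,
    kim_forger_f,
    neurospora_f,
    phospholock_f,
    rhs_core,
    rhs_phospholock,
    rhs_ttfl,
)

from conftest import random_neurospora, random_phospholock


# ---------------------------------------------------------------------------
# free_kaiA
# ---------------------------------------------------------------------------


class TestFreeKaiA:
    def test_no_sequestrant_zero_kd(self):
        assert free_kaiA(0.0, 8.0, 0.0) == pytest.approx(8.0)

    def test_tight_binding_limit(self):
        assert free_kaiA(4.0, 8.0, 0.0) == pytest.approx(4.0)
        assert free_kaiA(12.0, 8.0, 0.0) == pytest.approx(0.0, abs=1e-14)

    def test_against_bisection_oracle(self):
        # free A solves A*(S - A_T + A) = Kd*(A_T - A) on [0, A_T]
        S, A_T, Kd = 4.0, 8.0, 1e-2

        def balance(A):
            return A * (S - A_T + A) - Kd * (A_T - A)

        oracle = bisect(balance, 0.0, A_T, xtol=1e-12)
        assert free_kaiA(S, A_T, Kd) == pytest.approx(oracle, abs=1e-8)

    def test_negative_inputs_raise(self):
        with pytest.raises(DomainError):
            free_kaiA(-1.0, 8.0, 0.1)
        with pytest.raises(DomainError):
            free_kaiA(1.0, 8.0, -0.1)
        with pytest.raises(DomainError):
            free_kaiA(1.0, 0.0, 0.1)

    @given(S=st.floats(0, 200), A_T=st.floats(0.01, 150),
           Kd=st.floats(0, 0.5))
    @settings(max_examples=200, deadline=None)
    def test_bounds(self, S, A_T, Kd):
        f = free_kaiA(S, A_T, Kd)
        assert 0.0 <= f <= A_T + 1e-12

    def test_monotone_nonincreasing_dense_grid(self):
        S = np.linspace(0, 30, 4001)
        for Kd in (0.0, 1e-4, 1e-2, 0.5):
            f = free_kaiA(S, 8.0, Kd)
            assert np.all(np.diff(f) <= 1e-12)

    def test_kd_to_zero_limit(self):
        S = np.linspace(0, 20, 501)
        f = free_kaiA(S, 8.0, 1e-12)
        assert np.allclose(f, np.maximum(8.0 - S, 0.0), atol=1e-5)


class TestKimForger:
    def test_no_repressor(self):
        assert kim_forger_f(0.0, 10.0, 0.0) == pytest.approx(1.0)

    def test_exact_titration(self):
        assert kim_forger_f(10.0, 10.0, 0.0) == pytest.approx(0.0, abs=1e-14)

    def test_shared_quadratic_identity(self, rng):
        # fraction = amount / A for arbitrary (P, A, Kd)
        for _ in range(200):
            P = rng.uniform(0, 150)
            A = rng.uniform(0.1, 100)
            Kd = rng.uniform(0, 1)
            assert kim_forger_f(P, A, Kd) == pytest.approx(
                free_kaiA(P, A, Kd) / A, abs=1e-12, rel=1e-12)

    def test_zero_activator_raises(self):
        with pytest.raises(DomainError):
            kim_forger_f(1.0, 0.0, 0.1)


# ---------------------------------------------------------------------------
# phospholock / activator-phosphorylation repression functions
# ---------------------------------------------------------------------------


def _equilibrium_phospholock(p, R_T, rtol=1e-12):
    """ODE relaxation of the explicit subnetwork A+R<->AR<->ARp -(k3)-> A,
    with the repressor pool held at R_T (recycled on dissociation)."""

    def rhs(t, y):
        A, AR, ARp, Rf = y
        v1 = p.k1f * A * Rf - p.k1r * AR
        v2 = p.k2f * AR - p.k2r * ARp
        v3 = p.k3 * ARp
        return [-v1 + v3, v1 - v2, v2 - v3, -v1 + v3]

    sol = solve_ivp(rhs, (0.0, 2e6), [p.A_T, 0.0, 0.0, R_T],
                    method="LSODA", rtol=rtol, atol=1e-12)
    assert sol.success
    return sol.y[0, -1]


def _equilibrium_neurospora(p, R_T, rtol=1e-12):
    """As above plus A<->Ap and phosphorylated-activator release
    ARp -(k3)-> Ap + R."""

    def rhs(t, y):
        A, Ap, AR, ARp, Rf = y
        v1 = p.k1f * A * Rf - p.k1r * AR
        v2 = p.k2f * AR - p.k2r * ARp
        v3 = p.k3 * ARp
        v4 = p.k4f * A - p.k4r * Ap
        return [-v1 - v4, v4 + v3, v1 - v2, v2 - v3, -v1 + v3]

    sol = solve_ivp(rhs, (0.0, 2e6), [p.A_T, 0.0, 0.0, 0.0, R_T],
                    method="LSODA", rtol=rtol, atol=1e-12)
    assert sol.success
    return sol.y[0, -1]


class TestPhospholockF:
    def test_value_at_zero(self, table1_phospholock):
        p = table1_phospholock
        assert phospholock_f(0.0, p) == pytest.approx(p.A_T, rel=1e-12)

    def test_tail_bound(self, table1_phospholock):
        p = table1_phospholock
        K1, K2 = effective_constants(p)
        for R in (1e4, 1e6):
            f = phospholock_f(R, p)
            assert 0.0 < f < p.A_T * (K2 / K1) / R * 2.0

    def test_strictly_decreasing(self, table1_phospholock):
        R = np.linspace(0, 300, 2000)
        f = phospholock_f(R, table1_phospholock)
        assert np.all(np.diff(f) < 0)

    def test_equilibrium_oracle_reference_params(self, table1_phospholock):
        p = table1_phospholock
        f = phospholock_f(100.0, p)
        oracle = _equilibrium_phospholock(p, 100.0)
        assert f == pytest.approx(oracle, rel=1e-6)

    def test_no_lock_reduces_to_sequestration(self, rng):
        p = random_phospholock(rng, k2f=0.0, k3=0.0)
        R = np.linspace(0, 2 * p.A_T, 50)
        assert np.allclose(phospholock_f(R, p),
                           free_kaiA(R, p.A_T, p.k1r / p.k1f), rtol=1e-12)

    def test_equilibrium_oracle_randomized(self, rng):
        worst = 0.0
        for _ in range(100):
            p = random_phospholock(rng)
            R_T = rng.uniform(0.1, 2 * p.A_T)
            f = phospholock_f(R_T, p)
            oracle = _equilibrium_phospholock(p, R_T)
            worst = max(worst, abs(f - oracle) / max(oracle, 1e-12))
        assert worst < 1e-6


class TestNeurosporaF:
    def test_reduces_to_phospholock_at_zero_k4(self, table1_phospholock):
        p = table1_phospholock
        n = NeurosporaParams(
            alpha1=p.alpha1, beta1=p.beta1, alpha2=p.alpha2, beta2=p.beta2,
            alpha3=p.alpha3, beta3=p.beta3, A_T=p.A_T, k1f=p.k1f, k1r=p.k1r,
            k2f=0.0, k2r=p.k2r, k3=p.k3, k4f=0.0, k4r=1.0)
        e = models.PhospholockParams(
            alpha1=p.alpha1, beta1=p.beta1, alpha2=p.alpha2, beta2=p.beta2,
            alpha3=p.alpha3, beta3=p.beta3, A_T=p.A_T, k1f=p.k1f, k1r=p.k1r,
            k2f=0.0, k2r=p.k2r, k3=p.k3)
        R = np.linspace(0, 2 * p.A_T, 200)
        assert np.allclose(neurospora_f(R, n), phospholock_f(R, e), rtol=0,
                           atol=1e-12 * p.A_T)
        assert neurospora_f(0.0, n) == pytest.approx(p.A_T, rel=1e-12)

    def test_value_at_zero_with_k4(self, neuro_params):
        p = neuro_params
        assert p.k4 == pytest.approx(1.0)
        assert neurospora_f(0.0, p) == pytest.approx(p.A_T / 2.0, rel=1e-12)

    def test_decreasing(self, neuro_params):
        R = np.linspace(0, 400, 2000)
        f = neurospora_f(R, neuro_params)
        assert np.all(np.diff(f) < 1e-12)

    def test_equilibrium_oracle_sampled_params(self, rng):
        worst = 0.0
        for _ in range(100):
            p = random_neurospora(rng)
            R_T = rng.uniform(0.1, 2 * p.A_T)
            f = neurospora_f(R_T, p)
            oracle = _equilibrium_neurospora(p, R_T)
            worst = max(worst, abs(f - oracle) / max(oracle, 1e-12))
        assert worst < 1e-6

    def test_single_point_oracle(self, rng):
        p = random_neurospora(rng)
        assert neurospora_f(50.0, p) == pytest.approx(
            _equilibrium_neurospora(p, 50.0), rel=1e-6)


class TestEffectiveConstants:
    def test_no_lock_collapses_to_bare_kd(self, rng):
        p = random_phospholock(rng, k2f=0.0, k3=0.0)
        K1, K2 = effective_constants(p)
        assert K2 / K1 == pytest.approx(p.k1r / p.k1f, rel=1e-12)

    def test_sharpening_with_k2_at_unit_kd(self, table1_phospholock):
        # larger k2f/k2r ratios tighten the effective dissociation constant
        import dataclasses

        kds = []
        for k2 in (1.0, 10.0, 100.0, 1000.0):
            p = dataclasses.replace(table1_phospholock, k2f=k2, k2r=1.0)
            K1, K2 = effective_constants(p)
            kds.append(K2 / K1)
        assert all(a > b for a, b in zip(kds, kds[1:]))

    def test_scale_invariance_of_f(self, neuro_params):
        # f depends on the constants only through their joint ray
        K1, K2, K3 = effective_constants(neuro_params)
        f1 = models._repression_quadratic(37.0, neuro_params.A_T, K1, K2, K3,
                                          neuro_params.k4)
        f2 = models._repression_quadratic(37.0, neuro_params.A_T, 7 * K1,
                                          7 * K2, 7 * K3, neuro_params.k4)
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_k4r_guard(self, rng):
        with pytest.raises(DomainError):
            effective_constants(random_neurospora(rng, k4f=1.0, k4r=0.0))


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------


@pytest.fixture
def core_params():
    return CoreKaiParams(k1=0.5, k2=0.15, k3=0.15, k4=0.15, Kd=1e-4,
                         A_T=20.0, C_T=80.0)


class TestRhsCore:
    def test_cold_start(self, core_params):
        p = core_params
        d = rhs_core(0.0, np.zeros(3), p)
        assert d[0] == pytest.approx(p.k1 * free_kaiA(0, p.A_T, p.Kd) * p.C_T)
        assert d[1] == 0.0
        assert d[2] == 0.0

    def test_chain_steady_state_relation(self, core_params):
        # at dST = 0: k2*T = k3*ST
        p = core_params
        T = 4.0
        ST = p.k2 * T / p.k3
        d = rhs_core(0.0, np.array([T, ST, 1.0]), p)
        assert d[1] == pytest.approx(0.0, abs=1e-12)


class TestRhsTtfl:
    @pytest.fixture
    def params(self):
        return TTFLParams(k1=0.1, k2=0.15, k3=0.15, k4=0.15, Kd=1e-5,
                          A_T=30.0, V_trsp=0.17, V_m=0.5, K_s=40.0,
                          K_0=100.0, V_d=0.05, mode="ttfl")

    def test_hill_term_at_zero_s(self, params):
        y = np.array([2.0, 0, 0, 0, 0.0])
        d = rhs_ttfl(0.0, y, params)
        assert d[0] == pytest.approx(100.0 * params.V_trsp - params.V_m * 2.0)

    def test_half_maximal_at_threshold(self, params):
        y = np.array([0.0, 0, 0, 0, params.K_0])
        d = rhs_ttfl(0.0, y, params)
        assert d[0] == pytest.approx(50.0 * params.V_trsp)

    def test_constitutive_mode_ignores_s(self, params):
        ptr = params.as_mode("ptr")
        for S in (0.0, params.K_0, 250.0):
            y = np.array([3.0, 0, 0, 0, S])
            d = rhs_ttfl(0.0, y, ptr)
            assert d[0] == pytest.approx(ptr.V_trsp - ptr.V_m * 3.0)


class TestRhsChain:
    def test_cold_start_produces_mrna_only(self, table1_phospholock):
        p = table1_phospholock
        d = rhs_phospholock(0.0, np.zeros(3), p)
        assert d[0] == pytest.approx(p.alpha1 * p.A_T)
        assert d[1] == 0.0 and d[2] == 0.0

    def test_fixed_point_relation(self, table1_phospholock):
        # at steady state a1*a2*a3*f(R*) = b1*b2*b3*R*
        p = table1_phospholock
        from circlock.analysis import steady_state_repressor

        n = NeurosporaParams(
            alpha1=p.alpha1, beta1=p.beta1, alpha2=p.alpha2, beta2=p.beta2,
            alpha3=p.alpha3, beta3=p.beta3, A_T=p.A_T, k1f=p.k1f, k1r=p.k1r,
            k2f=p.k2f, k2r=p.k2r, k3=p.k3, k4f=0.0, k4r=1.0)
        R_star, _ = steady_state_repressor(n)
        lhs = p.alpha1 * p.alpha2 * p.alpha3 * neurospora_f(R_star, n)
        rhs_ = p.beta1 * p.beta2 * p.beta3 * R_star
        assert lhs == pytest.approx(rhs_, rel=1e-8)

    def test_kim_forger_dispatch(self):
        p = KimForgerParams(alpha1=10, alpha2=10, alpha3=10, beta1=1, beta2=1,
                            beta3=1, A=10.0, Kd=0.1)
        d = rhs_phospholock(0.0, np.array([0.0, 0.0, 5.0]), p)
        assert d[0] == pytest.approx(10 * kim_forger_f(5.0, 10.0, 0.1))

    def test_kernel_vector_matches_python(self, neuro_params, rng):
        from circlock import _kernels
        from circlock.models import chain_param_vector

        pvec = chain_param_vector(neuro_params)
        for _ in range(10):
            y = rng.uniform(0, 50, 3)
            out = np.empty(3)
            _kernels.rhs_chain.py_func(0.0, y, pvec, out)
            assert np.allclose(out, rhs_phospholock(0.0, y, neuro_params),
                               rtol=1e-12)


class TestParamValidation:
    def test_core_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            CoreKaiParams(k1=0, k2=1, k3=1, k4=1, Kd=0.1, A_T=1, C_T=1)

    def test_derived_quantities_recomputed(self, table1_phospholock):
        assert table1_phospholock.Kd == pytest.approx(1.0)
        assert table1_phospholock.k2 == pytest.approx(10.0)

    def test_ttfl_mode_validation(self):
        with pytest.raises(ValueError):
            TTFLParams(k1=1, k2=1, k3=1, k4=1, Kd=0.1, A_T=1, V_trsp=1,
                       V_m=1, K_s=1, K_0=1, V_d=1, mode="bogus")
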