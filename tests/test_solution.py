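"""Tests for the closed-form trajectories, equilibria and stability analysis.

The independent oracle for the closed form is classical fourth-order
Runge-Kutta integration of the nondimensional ODE system at a small fixed
step; the closed form must agree with it to tight absolute tolerance.
"""

import cmath

import numpy as np
import pytest

from aglif import (
    ModelState,
    NondimensionalParameters,
    auxiliary_terms,
    clamped_equilibrium,
    classify_stability,
    complete_parameters,
    eigenvalues,
    equilibria,
    general_integral,
    nondimensionalize,
    trajectory,
    voltage_sensitivities,
)


def nd(alpha, beta, delta, Vth=-0.72, Vr=-0.85):
    return NondimensionalParameters(
        alpha=alpha, beta=beta, delta=delta, tau=10.0,
        Vth_tilde=Vth, Vr_tilde=Vr, alpha_th=0.05,
    )


def rk4_oracle(alpha, beta, delta, x0, t_end, h=1e-3):
    """Vectorized RK4 integration of the nondimensional system."""
    x = np.array(x0, dtype=float)

    def f(x):
        V, Ia, Id = x
        return np.array([
            alpha + beta * (Id - Ia) + delta * (1.0 + V),
            1.0 - Ia + V,
            -beta * Id,
        ])

    def step(x, h):
        k1 = f(x)
        k2 = f(x + 0.5 * h * k1)
        k3 = f(x + 0.5 * h * k2)
        k4 = f(x + h * k3)
        return x + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

    n_steps = int(t_end / h)
    for _ in range(n_steps):
        x = step(x, h)
    rem = t_end - n_steps * h
    if rem > 0:
        x = step(x, rem)
    return x


class TestAuxiliaryTerms:
    def test_zero_elapsed_identity(self):
        aux = auxiliary_terms(0.3, 0.2, 0.0)
        assert aux.H1 == 0.0
        assert aux.H2 == 2.0
        assert aux.B_cal == 0.0 and aux.C_cal == 0.0

    def test_real_values_in_oscillatory_regime(self):
        aux = auxiliary_terms(2.0, 0.5, 1.3)
        assert aux.A_cal < 0
        assert isinstance(aux.H1, float) and isinstance(aux.H2, float)

    def test_degenerate_discriminant_limit(self):
        # at the parabola A = 0 the quotient H1 tends to dt * e^{(delta-1)dt/2};
        # evaluations at A = +/- 1e-12 offsets must agree with the limit
        delta, dt = 0.4, 1.7
        beta0 = (delta + 1.0) ** 2 / 4.0
        lim = dt * np.exp(0.5 * (delta - 1.0) * dt)
        assert auxiliary_terms(beta0, delta, dt).H1 == pytest.approx(lim, abs=1e-10)
        for off in (+1e-12, -1e-12):
            aux = auxiliary_terms(beta0 - off / 4.0, delta, dt)
            assert aux.H1 == pytest.approx(lim, abs=1e-8)

    def test_matches_direct_complex_evaluation(self):
        beta, delta, dt = 0.3, 0.2, 1.0
        A = (delta + 1) ** 2 - 4 * beta
        sA = cmath.sqrt(A)
        B = -0.5 * (sA - delta + 1) * dt
        C = sA * dt
        H1 = cmath.exp(B) * (cmath.exp(C) - 1) / sA
        H2 = cmath.exp(B) * (cmath.exp(C) + 1)
        aux = auxiliary_terms(beta, delta, dt)
        assert aux.H1 == pytest.approx(H1.real, rel=1e-12)
        assert aux.H2 == pytest.approx(H2.real, rel=1e-12)


class TestGeneralIntegral:
    def test_initial_instant_returns_initial_data(self):
        n = nd(0.3, 0.4, 0.2)
        init = ModelState(t=1.0, V=-0.9, I_adap=0.2, I_dep=0.4,
                          units_flag="nondimensional")
        out = general_integral(n, init, 1.0, 1.0)
        assert (out.V, out.I_adap, out.I_dep) == (init.V, init.I_adap, init.I_dep)

    def test_depolarizing_current_decays_exponentially(self):
        n = nd(0.0, 0.5, 0.2)
        init = ModelState(t=0.0, V=-1.0, I_adap=0.0, I_dep=1.0,
                          units_flag="nondimensional")
        out = general_integral(n, init, 0.0, 2.0)
        assert out.I_dep == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_backwards_time_rejected(self):
        n = nd(0.0, 0.5, 0.2)
        init = ModelState(t=1.0, V=-1.0, I_adap=0.0, I_dep=0.0,
                          units_flag="nondimensional")
        with pytest.raises(ValueError):
            general_integral(n, init, 1.0, 0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_rk4_on_stable_draws(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            delta = rng.uniform(0.05, 0.95)
            band = (1 + delta) ** 2 / 4.0 - delta
            beta = delta + rng.uniform(0.05, 1.0) * band
            alpha = rng.uniform(-0.5, 0.8)
            x0 = rng.uniform([-1.3, 0.0, 0.0], [-0.2, 1.0, 1.0])
            t_end = rng.uniform(1.0, 8.0)
            n = nd(alpha, beta, delta)
            got = np.array(trajectory(n, *x0, 0.0, t_end))
            want = rk4_oracle(alpha, beta, delta, x0, t_end)
            assert np.allclose(got, want, atol=1e-6)

    def test_degenerate_beta_equals_delta_matches_rk4(self):
        beta = delta = 0.3
        n = nd(0.4, beta, delta)
        got = np.array(trajectory(n, -0.9, 0.2, 0.1, 0.0, 3.0))
        want = rk4_oracle(0.4, beta, delta, [-0.9, 0.2, 0.1], 3.0)
        assert np.allclose(got, want, atol=1e-6)

    def test_degenerate_resonance_matches_rk4(self):
        # beta^2 + (beta-1) delta = 0: depolarizing decay rate equals a
        # membrane eigenvalue
        delta = 0.8
        beta = (-delta + np.sqrt(delta**2 + 4 * delta)) / 2.0
        n = nd(0.3, beta, delta)
        got = np.array(trajectory(n, -1.1, 0.3, 0.7, 0.0, 2.5))
        want = rk4_oracle(0.3, beta, delta, [-1.1, 0.3, 0.7], 2.5)
        assert np.allclose(got, want, atol=1e-6)

    def test_converges_to_equilibrium(self):
        n = nd(0.2, 0.5, 0.3)
        eq = equilibria(n)[0]
        lam = eigenvalues(n.beta, n.delta)
        rate = max(ev.real for ev in lam)
        t_end = 200.0 / abs(rate)
        V, Ia, Id = trajectory(n, -0.9, 0.1, 0.2, 0.0, t_end)
        assert V == pytest.approx(eq.V_star, abs=1e-6)
        assert Ia == pytest.approx(eq.I_adap_star, abs=1e-6)
        assert Id == pytest.approx(0.0, abs=1e-6)


class TestEquilibria:
    def test_generic_equilibrium_by_substitution(self):
        eq = equilibria(nd(0.1, 0.3, 0.1))[0]
        assert eq.kind == "E1"
        assert eq.V_star == pytest.approx(-0.5)
        assert eq.I_adap_star == pytest.approx(0.5)
        assert eq.I_dep_star == 0.0
        # structural relation I_adap* - V* = 1
        assert eq.I_adap_star - eq.V_star == pytest.approx(1.0)

    def test_equilibrium_family_at_zero_current(self):
        eqs = equilibria(nd(0.0, 0.5, 0.5))
        assert eqs[0].kind == "E0_family"
        assert (eqs[0].V_star, eqs[0].I_adap_star, eqs[0].I_dep_star) == (-1.0, 0.0, 0.0)

    def test_zero_current_generic_reduces_to_rest(self):
        eq = equilibria(nd(0.0, 0.3, 0.1))[0]
        assert eq.kind == "E1"
        assert (eq.V_star, eq.I_adap_star, eq.I_dep_star) == (-1.0, 0.0, 0.0)


class TestEigenvalues:
    def test_first_eigenvalue_is_minus_beta(self):
        for beta, delta in [(0.3, 0.2), (1.7, 0.9), (2.5, 1.4)]:
            assert eigenvalues(beta, delta)[0] == -beta

    def test_real_pair_value(self):
        l1, l2, l3 = eigenvalues(0.3, 0.2)
        assert l2.real == pytest.approx((-0.8 + np.sqrt(0.24)) / 2.0)
        assert l2.imag == 0.0

    def test_pure_imaginary_pair(self):
        _, l2, l3 = eigenvalues(2.0, 1.0)
        assert l2 == pytest.approx(1j)
        assert l3 == pytest.approx(-1j)

    def test_agrees_with_numeric_jacobian(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            beta, delta = rng.uniform(0.05, 3.0, size=2)
            M = np.array([[delta, -beta, beta], [1.0, -1.0, 0.0], [0.0, 0.0, -beta]])
            want = sorted(np.linalg.eigvals(M), key=lambda z: (z.real, z.imag))
            got = sorted(eigenvalues(beta, delta), key=lambda z: (z.real, z.imag))
            assert np.allclose(got, want, atol=1e-10)

    def test_independent_of_alpha(self):
        # the spectrum is a function of (beta, delta) only; trajectories for
        # different alpha decay toward their equilibria at identical rates
        for alpha in (-1.0, 0.0, 1.0):
            n = nd(alpha, 0.5, 0.3)
            assert eigenvalues(n.beta, n.delta) == eigenvalues(0.5, 0.3)


class TestClassifyStability:
    @pytest.mark.parametrize(
        "beta,delta,label",
        [
            (0.3, 0.2, "stable_node_real"),
            (1.0, 0.5, "stable_focus_damped"),
            (2.0, 1.5, "unstable"),
            (0.25, 0.5, "unstable"),
            (2.0, 1.0, "center_sustained"),
            (0.5, 0.5, "boundary_degenerate"),
        ],
    )
    def test_region_examples(self, beta, delta, label):
        assert classify_stability(beta, delta).label == label

    def test_label_consistent_with_eigenvalues(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            beta, delta = rng.uniform(0.02, 3.0, size=2)
            rep = classify_stability(beta, delta)
            reals = [ev.real for ev in rep.eigenvalues]
            if rep.label in ("stable_node_real", "stable_focus_damped"):
                assert max(reals) < 1e-12
            elif rep.label == "unstable":
                assert max(reals) > -1e-12
            elif rep.label == "center_sustained":
                assert max(abs(r) for r in reals[1:]) < 1e-12


class TestVoltageSensitivities:
    def setup_method(self):
        self.n = nd(0.2, 0.3, 0.2)
        self.init = ModelState(t=0.0, V=-0.9, I_adap=0.3, I_dep=0.2,
                               units_flag="nondimensional")

    def test_zero_at_initial_instant(self):
        da, dd = voltage_sensitivities(self.n, self.init, 0.0, 0.0)
        assert da == 0.0
        assert dd == pytest.approx(0.0, abs=1e-9)

    def test_adaptation_sensitivity_negative(self):
        da, _ = voltage_sensitivities(self.n, self.init, 0.0, 5.0)
        assert da < 0

    def test_depolarization_sensitivity_positive(self):
        _, dd = voltage_sensitivities(self.n, self.init, 0.0, 5.0)
        assert dd > 0

    def test_closed_form_matches_finite_difference(self):
        da, _ = voltage_sensitivities(self.n, self.init, 0.0, 3.0)
        h = 1e-6
        Vp = trajectory(self.n, self.init.V, self.init.I_adap + h, self.init.I_dep, 0.0, 3.0)[0]
        Vm = trajectory(self.n, self.init.V, self.init.I_adap - h, self.init.I_dep, 0.0, 3.0)[0]
        assert da == pytest.approx(float(Vp - Vm) / (2 * h), rel=1e-5)


class TestClampedEquilibrium:
    @pytest.fixture(autouse=True)
    def _params(self):
        # k_1 = 0.03 gives beta = 0.3 != delta = 0.5, so the unclamped
        # equilibrium is well defined for subthreshold positive currents
        self.p = complete_parameters(
            dict(E_L=-70.0, V_r=-60.0, V_th=-50.0, C_m=100.0, tau_m=20.0,
                 I_th=140.0, K=700.0, k_1=0.03, I_stim_neg=-185.0)
        )

    def test_zero_current_rests_at_leak_potential(self):
        _, mV = clamped_equilibrium(0.0, self.p)
        assert mV == pytest.approx(self.p.E_L)

    def test_reference_negative_current_reaches_floor(self):
        _, mV = clamped_equilibrium(-185.0, self.p)
        assert mV == pytest.approx(-90.0)

    def test_linear_interpolation_at_midpoint(self):
        _, mV = clamped_equilibrium(-92.5, self.p)
        assert mV == pytest.approx(-80.0)

    def test_saturates_below_reference_current(self):
        _, mV = clamped_equilibrium(-500.0, self.p)
        assert mV == pytest.approx(-90.0)

    def test_subthreshold_positive_uses_unclamped_equilibrium(self):
        n = nondimensionalize(self.p, 70.0)
        V_star, _ = clamped_equilibrium(70.0, self.p, n)
        assert V_star == pytest.approx(n.alpha / (n.beta - n.delta) - 1.0)

    def test_suprathreshold_rejected(self):
        with pytest.raises(ValueError):
            clamped_equilibrium(200.0, self.p)
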