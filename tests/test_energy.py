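"""Helmholtz split, Hamiltonian energy, energy rate and summaries.

The module's load-bearing identities are checked along two independent
routes: numerically at 10^4 random states, and symbolically with sympy
(exact algebra, no tolerances).
"""

import numpy as np
import pytest

from hrenergy import (CouplingSpec, EnergyRecord, HRParams, IntegratorConfig,
                      energy_series, energy_summary, equilibrium_uncoupled,
                      grad_hamiltonian, hamiltonian, hdot_formula,
                      hdot_printed_polynomial, helmholtz_split, integrate,
                      orthogonality_residual, rhs_reduced)


def _u(states, coupling):
    D = np.asarray(coupling.D)
    return (states[..., 1] - states[..., 2]
            + D * (np.asarray(coupling.x0) - states[..., 0]))


@pytest.mark.parametrize("state, D, x0, expected", [
    ((0, 0, 0), 0.0, 0.0, 0.0),
    ((1, 1, 1), 0.0, 0.0, 10.0 / 3.0 + 0.04),          # u = 0
    ((1, 2, 0), 1.0, 1.0, 4.0 + 10.0 / 3.0 + 0.04),    # u = 2
])
def test_hamiltonian_closed_form(state, D, x0, expected, params):
    c = CouplingSpec.from_aggregate(D=D, x0=x0)
    assert hamiltonian(np.array(state, float), params, c) == pytest.approx(
        expected, abs=1e-12)
    assert hamiltonian(np.array(state, float), params, c,
                       scaled=True) == pytest.approx(expected / 100, abs=1e-14)


class TestGradient:
    def test_conventions_agree_at_zero_coupling(self, params, random_states):
        c = CouplingSpec.from_aggregate(D=0.0, x0=2.0)
        g_p = grad_hamiltonian(random_states, params, c, "partial")
        g_f = grad_hamiltonian(random_states, params, c, "full")
        np.testing.assert_array_equal(g_p, g_f)

    def test_gradient_at_u_zero(self, params):
        # y = z and x = x0 kill u; only the x-component survives
        state = np.array([1.5, 0.7, 0.7])
        c = CouplingSpec.from_aggregate(D=2.0, x0=1.5)
        g = grad_hamiltonian(state, params, c, "partial")
        expected_x = 2 * params.d * 1.5**2 + 2 * params.r * params.s * 1.5
        np.testing.assert_allclose(g, [expected_x, 0.0, 0.0], atol=1e-12)

    def test_partial_gradient_matches_central_difference(self, params, coupling):
        """O(h^2) central differences of H with the drive q = D(x0-x) frozen."""
        state = np.array([0.8, -0.4, 1.2])
        q = float(np.asarray(coupling.D) * (coupling.x0 - state[0]))

        def H_frozen_drive(s):
            u = s[1] - s[2] + q
            return (u**2 + (2 / 3) * params.d * s[0]**3
                    + params.r * params.s * s[0]**2)

        h = 1e-6
        fd = np.empty(3)
        for i in range(3):
            e = np.zeros(3)
            e[i] = h
            fd[i] = (H_frozen_drive(state + e) - H_frozen_drive(state - e)) / (2 * h)
        g = grad_hamiltonian(state, params, coupling, "partial")
        np.testing.assert_allclose(g, fd, rtol=1e-7, atol=1e-7)


class TestHelmholtzSplit:
    def test_F1_vanishes_at_origin_without_coupling(self, params):
        c = CouplingSpec.from_aggregate(D=0.0, x0=0.0)
        sp = helmholtz_split(np.zeros(3), params, c)
        np.testing.assert_array_equal(sp.F1, np.zeros(3))

    def test_consistent_variant_completes_the_vector_field(
            self, params, coupling, random_states):
        sp = helmholtz_split(random_states, params, coupling, "consistent")
        rhs = rhs_reduced(random_states, params, coupling)
        assert np.abs(sp.F1 + sp.F2 - rhs).max() < 1e-12

    def test_as_printed_variant_differs_by_minus_kx(self, params, random_states):
        c = CouplingSpec(d1=0.5, k=2.0, x0=1.0)
        sp = helmholtz_split(random_states, params, c, "as_printed")
        rhs = rhs_reduced(random_states, params, c)
        gap = sp.F1 + sp.F2 - rhs
        np.testing.assert_allclose(gap[..., 0], -2.0 * random_states[..., 0],
                                   atol=1e-12)
        assert np.abs(gap[..., 1:]).max() < 1e-12

    def test_unknown_variant_rejected(self, params, coupling):
        with pytest.raises(ValueError, match="variant"):
            helmholtz_split(np.zeros(3), params, coupling, "bogus")


class TestOrthogonality:
    def test_zero_coupling_both_conventions(self, params, random_states):
        c = CouplingSpec.from_aggregate(D=0.0, x0=1.0)
        for conv in ("partial", "full"):
            r = orthogonality_residual(random_states, params, c, conv)
            assert np.abs(r).max() < 1e-10

    def test_partial_convention_identity(self, params, random_states):
        """grad H . F1 = 0 under the partial convention: the core identity."""
        rng = np.random.default_rng(7)
        Ds = rng.uniform(0, 5, size=len(random_states))
        c = CouplingSpec.from_aggregate(D=Ds, x0=1.3)
        r = orthogonality_residual(random_states, params, c, "partial")
        assert np.abs(r).max() < 1e-10

    def test_full_convention_equals_minus_2Du2(self, params, random_states):
        rng = np.random.default_rng(8)
        Ds = rng.uniform(0, 5, size=len(random_states))
        c = CouplingSpec.from_aggregate(D=Ds, x0=-0.4)
        r = orthogonality_residual(random_states, params, c, "full")
        expected = -2.0 * Ds * _u(random_states, c)**2
        np.testing.assert_allclose(r, expected, rtol=1e-10, atol=1e-12)

    def test_full_convention_spot_value(self, params):
        # u = 1, D = 2 -> residual -4
        state = np.array([0.0, 1.0, 0.0])
        c = CouplingSpec.from_aggregate(D=2.0, x0=0.0)
        assert orthogonality_residual(state, params, c, "full") == pytest.approx(-4.0)


class TestHdot:
    def test_matches_printed_polynomial(self, random_states):
        """Dot-product route vs the transcribed polynomial expansion."""
        p = HRParams(I_ext=1.0)
        c = CouplingSpec(d1=0.7, k=3.0, x0=1.3)
        a = hdot_formula(random_states, p, c, "as_printed")
        b = hdot_printed_polynomial(random_states, p, c)
        scale = np.abs(b).max()
        assert np.abs(a - b).max() / scale < 1e-9

    def test_zero_at_uncoupled_equilibrium(self, params):
        eq = equilibrium_uncoupled(params)
        c = CouplingSpec.from_aggregate(D=0.0, x0=0.0)
        assert abs(hdot_formula(eq.state, params, c, "consistent")) < 1e-9

    def test_variant_difference_closed_form(self, params, random_states):
        """Hdot_printed - Hdot_consistent = -k x (2 d x^2 + 2 r s x) exactly."""
        c = CouplingSpec(d1=0.5, k=4.0, x0=0.2)
        x = random_states[..., 0]
        diff = (hdot_formula(random_states, params, c, "as_printed")
                - hdot_formula(random_states, params, c, "consistent"))
        expected = -4.0 * x * (2 * params.d * x**2
                               + 2 * params.r * params.s * x)
        np.testing.assert_allclose(diff, expected, rtol=1e-9, atol=1e-9)


def test_identities_hold_symbolically():
    """Exact sympy verification of orthogonality, completeness and Hdot."""
    import sympy as sp

    x, y, z, a, b, c, d, r, s, xr, I, D, x0, k, d1 = sp.symbols(
        "x y z a b c d r s x_r I D x_0 k d_1")
    u = y - z + D * (x0 - x)
    H = u**2 + sp.Rational(2, 3) * d * x**3 + r * s * x**2
    grad_partial = sp.Matrix([2 * d * x**2 + 2 * r * s * x, 2 * u, -2 * u])
    F1 = sp.Matrix([u, -d * x**2, r * s * x])
    F2c = sp.Matrix([-a * x**3 + b * x**2 + I, c - y, -r * s * xr - r * z])
    rhs = sp.Matrix([
        y - a * x**3 + b * x**2 + I - z + D * (x0 - x),
        c - d * x**2 - y,
        r * (s * (x - xr) - z),
    ])
    assert sp.simplify(grad_partial.dot(F1)) == 0
    assert sp.simplify(F1 + F2c - rhs) == sp.zeros(3, 1)
    # full gradient picks up -2Du in x, so grad.F1 = -2Du^2
    grad_full = sp.Matrix([sp.diff(H, v) for v in (x, y, z)])
    assert sp.simplify(grad_full.dot(F1) + 2 * D * u**2) == 0
    # as-printed variant: substitute D = d1*k and compare with the package
    F2p = F2c + sp.Matrix([-k * x, 0, 0])
    hdot = sp.expand(grad_partial.dot(F2p).subs(D, d1 * k))
    subs = {x: 0.3, y: -0.7, z: 1.1, a: 1, b: 3, c: 1, d: 5,
            r: sp.Rational(1, 100), s: 4, xr: sp.Rational(-8, 5),
            I: 1, d1: sp.Rational(1, 2), k: 3, x0: sp.Rational(13, 10)}
    got = hdot_printed_polynomial(
        np.array([0.3, -0.7, 1.1]), HRParams(I_ext=1.0),
        CouplingSpec(d1=0.5, k=3.0, x0=1.3))
    assert float(hdot.subs(subs)) == pytest.approx(got, rel=1e-12)


class TestEnergySeries:
    def test_pinned_equilibrium_constant_H_zero_Hdot(self, params):
        eq = equilibrium_uncoupled(params)
        c = CouplingSpec.from_aggregate(D=0.0, x0=0.0)
        cfg = IntegratorConfig(dt=0.01, total_time=10.0)
        traj = integrate(lambda s: rhs_reduced(s, params, c), eq.state, cfg)
        rec = energy_series(traj, params, c, scaled=False)
        assert np.ptp(rec.H) < 1e-9
        assert np.abs(rec.Hdot).max() < 1e-7

    @pytest.mark.parametrize("D, x0", [(0.0, 0.0), (1.0, 1.0)])
    def test_chain_rule_converges_at_order_dt(self, params, D, x0):
        """d/dt H along the flow equals Hdot_consistent - 2 D u xdot.

        The centered difference of H along an Euler trajectory matches the
        closed form with an O(dt) defect from the integrator; halving dt
        should roughly halve the error.
        """
        c = CouplingSpec.from_aggregate(D=D, x0=x0)
        eq = equilibrium_uncoupled(params)
        init = eq.state + np.array([0.05, -0.03, 0.02])
        errs = []
        for dt in (0.01, 0.005, 0.0025):
            cfg = IntegratorConfig(dt=dt, total_time=50.0)
            traj = integrate(lambda s: rhs_reduced(s, params, c), init, cfg)
            rec = energy_series(traj, params, c, scaled=False)
            deriv = rhs_reduced(traj.states, params, c)
            u = _u(traj.states, c)
            formula = rec.Hdot - 2.0 * D * u * deriv[..., 0]
            fd = (rec.H[2:] - rec.H[:-2]) / (2 * dt)
            errs.append(np.abs(fd - formula[1:-1]).max())
        assert errs[1] < 0.75 * errs[0]
        assert errs[2] < 0.75 * errs[1]


class TestEnergySummary:
    def _record(self, t, H, Hdot):
        return EnergyRecord(times=t, H=H, Hdot=Hdot, variant="consistent",
                            scaled=False)

    def test_constant_series(self):
        t = np.linspace(0, 10, 1001)
        rec = self._record(t, np.full_like(t, 7.0), np.zeros_like(t))
        s = energy_summary(rec, 0.0, 10.0)
        assert s.H1 == pytest.approx(7.0)
        assert s.deltaH == 0.0
        assert s.H2 == (0.0, 0.0)

    def test_sine_over_whole_periods_averages_to_zero(self):
        t = np.arange(0, 4 * np.pi, 0.001)  # last sample just short of 4 pi
        rec = self._record(t, np.sin(t), np.cos(t))
        s = energy_summary(rec, 0.0, float(t[-1]))
        assert abs(s.H1) < 1e-6
        assert s.deltaHdot == pytest.approx(2.0, abs=1e-5)

    def test_window_out_of_range_rejected(self):
        t = np.linspace(0, 1, 11)
        rec = self._record(t, t, t)
        with pytest.raises(ValueError, match="window"):
            energy_summary(rec, 0.5, 2.0)
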