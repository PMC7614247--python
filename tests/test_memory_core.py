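"""Memory ingredients, propagator, memory function, kernels, random force."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp
from scipy.linalg import expm

import memnet as mn


def closed_form_ingredients_bistable2(x1, a=6.0, n=3.0):
    """Independent scalar-case algebra for the two-node switch:
    f0 = dR1/dx2, J = -1, l = -1 - (dR2/dx1)(dR1/dx2), c = -(dR2/dx1) R1."""
    x2 = a / (1 + x1 ** n)
    dR1_dx2 = -a * n * x2 ** (n - 1) / (1 + x2 ** n) ** 2
    dR2_dx1 = -a * n * x1 ** (n - 1) / (1 + x1 ** n) ** 2
    R1 = a / (1 + x2 ** n) - x1
    return dict(f0=dR1_dx2, J=-1.0, l=-1.0 - dR2_dx1 * dR1_dx2,
                c=-dR2_dx1 * R1, drift=R1, x2=x2)


class TestIngredients:
    def test_bistable2_scalar_closed_form(self, bistable2_calc):
        for x1 in (0.4, 1.1, 3.3):
            ing = bistable2_calc.ingredients([x1])
            ref = closed_form_ingredients_bistable2(x1)
            assert ing.f0[0, 0] == pytest.approx(ref["f0"], rel=1e-10)
            assert ing.J[0, 0] == pytest.approx(ref["J"], rel=1e-12)
            assert ing.l[0, 0] == pytest.approx(ref["l"], rel=1e-10)
            assert ing.c[0] == pytest.approx(ref["c"], rel=1e-10)

    def test_c_vanishes_at_saddle(self, bistable2_calc, bistable2_fps):
        saddle = bistable2_fps[1]
        ing = bistable2_calc.ingredients(saddle.location[[0]])
        assert abs(ing.c[0]) < 1e-10

    def test_finite_difference_cross_check(self, neural_tube):
        calc = mn.MemoryCalculator(neural_tube)
        x_s = np.array([0.8, 1.2])
        ing = calc.ingredients(x_s)
        q = calc.qss
        h = 1e-6
        # f0[b, s] = dR_s/dx_b at (x^s, x^b*) by central differences
        full = q._full_state(x_s, ing.x_b)
        for kb, b in enumerate(q._bulk):
            xp, xm = full.copy(), full.copy()
            xp[b] += h
            xm[b] -= h
            fd = (neural_tube.rates(xp) - neural_tube.rates(xm)) / (2 * h)
            assert np.allclose(ing.f0[kb], fd[q._sub], rtol=1e-5, atol=1e-8)

    def test_empty_bulk_degenerate(self, bistable2):
        part = mn.SubnetworkPartition((0, 1), ())
        calc = mn.MemoryCalculator(bistable2, part)
        x = np.array([1.0, 2.0])
        assert calc.ingredients(x).f0.size == 0
        ev = calc.memory(x, np.linspace(0, 5, 6))
        assert np.all(ev.M == 0)


class TestPropagator:
    def test_identity_at_zero(self, bistable2_calc, linear_bulk):
        assert np.allclose(bistable2_calc.propagator([2.0], 0.0), np.eye(1))
        calc2 = mn.MemoryCalculator(linear_bulk)
        assert np.allclose(calc2.propagator([1.0], 0.0), np.eye(2))

    def test_scalar_bulk_quadrature_oracle(self, bistable2_calc):
        # one bulk species: E(tau) = exp(int_0^tau l(phi(x, t')) dt')
        calc = bistable2_calc
        x0, tau = 3.0, 2.5
        flow = calc.qss.flow([x0], tau)
        integral, err = quad(
            lambda tp: calc.ingredients(flow(np.array(tp))).l[0, 0],
            0, tau, limit=200, epsabs=1e-12, epsrel=1e-12)
        E = calc.propagator([x0], tau)
        assert E[0, 0] == pytest.approx(np.exp(integral), abs=1e-8)

    def test_constant_generator_at_fixed_point(self, linear_bulk):
        calc = mn.MemoryCalculator(linear_bulk)
        fps = mn.find_fixed_points(linear_bulk, [(0, 5)], system="qss")
        x_star = fps[0].location
        l_star = calc.ingredients(x_star).l
        for tau in (0.5, 2.0):
            assert np.allclose(calc.propagator(x_star, tau),
                               expm(tau * l_star), atol=1e-8)


class TestMemoryFunction:
    def test_zero_at_every_fixed_point(self, bistable2_calc, bistable2_fps):
        taus = np.linspace(0, 50, 26)
        for fp in bistable2_fps:
            ev = bistable2_calc.memory(fp.location[[0]], taus)
            assert np.max(np.abs(ev.M)) < 1e-10

    def test_sign_opposite_to_drift(self, bistable2_calc):
        # between the saddle and the high state the drift is positive and
        # the memory delays relaxation: amplitude has the opposite sign
        for x1 in (2.0, 3.0, 5.0):
            v = bistable2_calc.qss.drift([x1])[0]
            m0 = bistable2_calc.memory([x1], 0.0).M[0, 0]
            assert np.sign(m0) == -np.sign(v)

    def test_memory_pde_residual(self, bistable2_calc):
        """The closed-form f_bs solves the memory transport PDE
        d_tau f = l(x) f + v(x) d_x f (method-of-lines residual)."""
        calc = bistable2_calc
        q = calc.qss

        def f_curve(x1, taus):
            ev = calc.memory(np.array([x1]), taus)
            f0y, _, _, _, _ = calc.ingredients_batch(ev.transported)
            return np.einsum("tbc,tcs->t", ev.E, f0y)

        h = 1e-4
        xs = np.linspace(2.0, 3.0, 7)
        taus = np.linspace(0.1, 2.0, 9)
        worst = 0.0
        for x1 in xs:
            f_mid = f_curve(x1, taus)
            f_tp = f_curve(x1, taus + h)
            f_tm = f_curve(x1, taus - h)
            f_xp = f_curve(x1 + h, taus)
            f_xm = f_curve(x1 - h, taus)
            d_tau = (f_tp - f_tm) / (2 * h)
            d_x = (f_xp - f_xm) / (2 * h)
            lv = calc.ingredients(np.array([x1])).l[0, 0]
            vv = q.drift([x1])[0]
            resid = d_tau - (lv * f_mid + vv * d_x)
            worst = max(worst, np.max(np.abs(resid)))
        assert worst < 1e-4

    def test_scalar_bulk_from_scratch_oracle(self, bistable2_calc):
        """Memory agrees with a from-scratch evaluation using only closed-form
        ingredients, scalar quadrature for E and a separate flow solve."""
        calc = bistable2_calc
        x1, tau = 2.4, 1.3
        ref = closed_form_ingredients_bistable2(x1)
        sol = solve_ivp(
            lambda t, y: [closed_form_ingredients_bistable2(y[0])["drift"]],
            (0, tau), [x1], rtol=1e-12, atol=1e-12, dense_output=True)
        y_tau = sol.sol(tau)[0]
        integral, _ = quad(
            lambda tp: closed_form_ingredients_bistable2(sol.sol(tp)[0])["l"],
            0, tau, limit=200, epsabs=1e-12)
        f0_at_y = closed_form_ingredients_bistable2(y_tau)["f0"]
        M_ref = ref["c"] * np.exp(integral) * f0_at_y
        M = calc.memory([x1], tau).M[0, 0]
        assert M == pytest.approx(M_ref, abs=1e-8)


class TestMemoryExport:
    def test_to_frame_columns(self, bistable2_calc):
        ev = bistable2_calc.memory([2.0], np.linspace(0, 3, 4))
        df = ev.to_frame(names=["x1"])
        assert list(df.columns) == ["x1", "tau", "M_x1"]
        assert len(df) == 4
        assert np.allclose(df["M_x1"].to_numpy(), ev.M[:, 0])


class TestLinearizedKernel:
    def test_requires_fixed_point(self, bistable2_calc):
        with pytest.raises(ValueError):
            bistable2_calc.linearized_kernel([2.0])

    def test_scalar_kernel_is_multiple_of_exp(self, bistable2_calc,
                                              bistable2_fps):
        K = bistable2_calc.linearized_kernel(bistable2_fps[2].location[[0]])
        l_star = K.l_star[0, 0]
        k0 = K(0.0)[0, 0]
        for tau in (0.5, 1.0, 3.0):
            assert K(tau)[0, 0] == pytest.approx(k0 * np.exp(l_star * tau),
                                                 rel=1e-12)

    def test_impulse_response_matches_full_linearized(self, bistable2,
                                                      bistable2_calc,
                                                      bistable2_fps):
        """The linearized projected system (drift Jacobian + convolution with
        K) reproduces the subnetwork impulse response of the full linearized
        system, with the bulk deviation initialized on the QSS manifold."""
        high = bistable2_fps[2]
        K = bistable2_calc.linearized_kernel(high.location[[0]])
        A = bistable2.jacobian(high.location)
        ds0 = 1e-3
        db0 = -A[1, 0] / A[1, 1] * ds0
        sol = solve_ivp(lambda t, z: A @ z, (0, 20), [ds0, db0],
                        rtol=1e-12, atol=1e-14, dense_output=True)
        # trapezoidal history integration of the convolution equation
        h = 0.002
        N = int(20 / h)
        Dv = K.drift_jacobian[0, 0]
        Kv = np.array([K(tau)[0, 0] for tau in h * np.arange(N + 1)])
        xs = np.zeros(N + 1)
        xs[0] = ds0
        for k in range(N):
            w = np.full(k + 1, h)
            w[0] = w[-1] = h / 2
            mem_k = np.sum(Kv[k - np.arange(k + 1)] * xs[:k + 1] * w) if k else 0.0
            f1 = Dv * xs[k] + mem_k
            xp = xs[k] + h * f1
            w2 = np.full(k + 2, h)
            w2[0] = w2[-1] = h / 2
            hist = np.append(xs[:k + 1], xp)
            mem_k1 = np.sum(Kv[(k + 1) - np.arange(k + 2)] * hist * w2)
            xs[k + 1] = xs[k] + h / 2 * (f1 + Dv * xp + mem_k1)
        ts = h * np.arange(N + 1)
        assert np.max(np.abs(xs - sol.sol(ts)[0])) < 1e-6 * ds0 / 1e-3

    def test_kernel_zero_for_decoupled_bulk(self):
        m = mn.build_model({
            "species": ["x1", "x2"],
            "rates": {"x1": "1 - x1", "x2": "x1 - 2*x2"},
            "params": {},
            "partition": {"sub": ["x1"], "bulk": ["x2"]},
        })
        calc = mn.MemoryCalculator(m)
        K = calc.linearized_kernel([1.0])
        for tau in (0.0, 1.0, 5.0):
            assert np.allclose(K(tau), 0.0, atol=1e-14)

    def test_kernel_decays_for_hurwitz_generator(self, bistable2_calc,
                                                 bistable2_fps):
        K = bistable2_calc.linearized_kernel(bistable2_fps[2].location[[0]])
        rate = abs(np.max(np.linalg.eigvals(K.l_star).real))
        tau_far = 25.0 / rate
        assert np.max(np.abs(K(tau_far))) < 1e-8


class TestRandomForce:
    def test_vanishes_at_qss(self, bistable2_calc):
        x_s = np.array([2.0])
        x_b = bistable2_calc.qss.solve(x_s)
        F = bistable2_calc.random_force(x_s, x_b, np.linspace(0, 5, 6))
        assert np.max(np.abs(F)) < 1e-12

    def test_tau_zero_linearizes_rate_deviation(self, linear_bulk):
        calc = mn.MemoryCalculator(linear_bulk)
        x_s = np.array([1.5])
        x_b_star = calc.qss.solve(x_s)
        delta = np.array([1e-4, -5e-5])
        x_b = x_b_star + delta
        F0 = calc.random_force(x_s, x_b, 0.0)
        full_dev = linear_bulk.rates(np.r_[x_s, x_b])[0] - \
            linear_bulk.rates(np.r_[x_s, x_b_star])[0]
        assert F0[0] == pytest.approx(full_dev, rel=1e-6)

    def test_linear_in_bulk_deviation(self, bistable2_calc):
        x_s = np.array([2.0])
        x_b_star = bistable2_calc.qss.solve(x_s)
        taus = np.linspace(0, 3, 7)
        F1 = bistable2_calc.random_force(x_s, x_b_star + 0.1, taus)
        F2 = bistable2_calc.random_force(x_s, x_b_star + 0.2, taus)
        assert np.allclose(F2, 2 * F1, rtol=1e-10)
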