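"""Full, QSS, ZMn and ZMs integrators and their cross-relations."""

import numpy as np
import pytest
from scipy.linalg import expm

import memnet as mn


class TestFull:
    def test_bistable2_converges_to_high_state(self, bistable2):
        traj = mn.integrate_full(bistable2, [1.55], 50.0,
                                 partition=bistable2.partition,
                                 bulk_at_qss=True)
        assert np.allclose(traj.states[-1], [6.000, 0.028], atol=1e-3)

    def test_linear_model_matches_matrix_exponential(self):
        m = mn.NetworkModel(["x1", "x2"],
                            {"x1": "-x1 + 0.3*x2", "x2": "0.2*x1 - 2*x2"}, {})
        A = np.array([[-1.0, 0.3], [0.2, -2.0]])
        x0 = np.array([1.0, -0.5])
        traj = mn.integrate_full(m, x0, 10.0, rtol=1e-11, atol=1e-13)
        for t in (0.5, 3.0, 10.0):
            assert np.allclose(traj(t), expm(A * t) @ x0, atol=1e-8)

    def test_requires_partition_for_subnetwork_x0(self, bistable2):
        with pytest.raises(ValueError):
            mn.integrate_full(bistable2, [1.0], 1.0)

    def test_repressilator_sustained_regime(self):
        # asymmetric start: the symmetric diagonal is invariant and would
        # converge to the (unstable) symmetric fixed point
        m = mn.build_model("repressilator", a=8.0, n=4.0)
        traj = mn.integrate_full(m, np.array([1.0, 0.8, 1.2]), 200.0)
        cl = mn.classify_oscillation(traj)
        assert cl.verdict == "sustained-oscillatory"
        assert cl.decay_ratio == pytest.approx(1.0, abs=0.01)


class TestQSS:
    def test_faster_than_full(self, bistable2):
        """The memoryless reduction underestimates transient duration."""
        full = mn.integrate_full(bistable2, [1.55], 80.0,
                                 partition=bistable2.partition,
                                 bulk_at_qss=True)
        qss = mn.integrate_qss(bistable2, bistable2.partition, [1.55], 80.0)
        target = 5.9999

        def time_to_within(traj, col, frac=0.01):
            ts = np.linspace(0, 80, 4000)
            x = traj(ts)[:, col]
            ok = np.abs(x - target) < frac * target
            return ts[np.argmax(ok)]

        assert time_to_within(qss, 0) < time_to_within(full, 0)

    def test_empty_bulk_identical_to_full(self, bistable2):
        part = mn.SubnetworkPartition((0, 1), ())
        x0 = np.array([2.0, 0.3])
        qss = mn.integrate_qss(bistable2, part, x0, 20.0)
        full = mn.integrate_full(bistable2, x0, 20.0)
        ts = np.linspace(0, 20, 100)
        assert np.allclose(qss(ts), full(ts), atol=1e-9)


class TestZMn:
    def test_tracks_full_better_than_qss(self, bistable2):
        """Near the saddle the memory-corrected reduction stays close to the
        full dynamics while the memoryless one relaxes too fast."""
        gap = 5.9999 - 0.0277
        ts = np.linspace(0, 50, 301)
        for x0 in (1.4, 2.0):
            full = mn.integrate_full(bistable2, [x0], 50.0,
                                     partition=bistable2.partition,
                                     bulk_at_qss=True, rtol=1e-10, atol=1e-12)
            zmn = mn.integrate_zmn(bistable2, bistable2.partition, [x0], 50.0,
                                   n_history=1000)
            qss = mn.integrate_qss(bistable2, bistable2.partition, [x0], 50.0)
            err_zmn = np.max(np.abs(full(ts)[:, 0] - zmn(ts)[:, 0])) / gap
            err_qss = np.max(np.abs(full(ts)[:, 0] - qss(ts)[:, 0])) / gap
            assert err_zmn < 0.05
            assert err_zmn < err_qss

    def test_memory_free_model_reduces_to_qss(self):
        # bulk decoupled from the subnetwork rate: f0 = dR_s/dx_b = 0
        m = mn.build_model({
            "species": ["x1", "x2"],
            "rates": {"x1": "2/(1 + x1^2) - x1", "x2": "x1 - x2"},
            "params": {},
            "partition": {"sub": ["x1"], "bulk": ["x2"]},
        })
        # the memory term is identically zero
        calc = mn.MemoryCalculator(m, m.partition)
        ev = calc.memory([0.7], np.linspace(0, 10, 11))
        assert np.max(np.abs(ev.M)) == 0.0
        # so the ZMn trajectory equals QSS up to its O(h^2) truncation error
        zmn = mn.integrate_zmn(m, m.partition, [0.2], 20.0, n_history=2000)
        qss = mn.integrate_qss(m, m.partition, [0.2], 20.0,
                               rtol=1e-11, atol=1e-13)
        ts = np.linspace(0, 20, 100)
        assert np.max(np.abs(zmn(ts) - qss(ts))) < 1e-4

    def test_history_step_second_order_convergence(self, bistable2):
        """Richardson self-convergence: halving h shrinks the change ~4x."""
        part = bistable2.partition
        sols = {}
        for nh in (125, 250, 500):
            sols[nh] = mn.integrate_zmn(bistable2, part, [2.0], 10.0,
                                        n_history=nh)
        ts = np.linspace(0, 10, 51)
        d1 = np.max(np.abs(sols[125](ts) - sols[250](ts)))
        d2 = np.max(np.abs(sols[250](ts) - sols[500](ts)))
        assert d2 < d1 / 2.5  # consistent with O(h^2)

    def test_empty_bulk_short_circuits(self, bistable2):
        part = mn.SubnetworkPartition((0, 1), ())
        x0 = np.array([1.0, 0.5])
        zmn = mn.integrate_zmn(bistable2, part, x0, 5.0)
        full = mn.integrate_full(bistable2, x0, 5.0)
        ts = np.linspace(0, 5, 20)
        assert np.allclose(zmn(ts), full(ts), atol=1e-9)


class TestZMs:
    def test_auxiliary_ode_matches_nested_quadrature(self, bistable2):
        """The auxiliary-ODE memory equals direct evaluation of the
        self-consistent double integral (product-of-exponentials propagator
        plus trapezoidal quadrature) along the same trajectory."""
        part = bistable2.partition
        calc = mn.MemoryCalculator(bistable2, part)
        traj = mn.integrate_zms(bistable2, part, [2.0], 5.0, calc=calc,
                                rtol=1e-11, atol=1e-13)
        t_checks = [1.0, 2.5, 5.0]
        mem_impl = mn.zms_memory_series(traj, t_checks)
        dt = 0.0005
        for idx, t in enumerate(t_checks):
            n = int(round(t / dt))
            tg = np.linspace(0.0, t, n + 1)
            XS = traj(tg)
            _, l_all, c_all, _, _ = calc.ingredients_batch(XS)
            # E(t', t) built backwards: E(t_j, t) = exp(dt*l_mid) E(t_{j+1}, t)
            E_acc = np.eye(calc.qss.n_bulk)
            m_vec = 0.5 * dt * c_all[n] @ E_acc
            for j in range(n - 1, -1, -1):
                l_mid = 0.5 * (l_all[j] + l_all[j + 1])
                E_acc = expm(dt * l_mid) @ E_acc
                w = 0.5 * dt if j == 0 else dt
                m_vec = m_vec + w * c_all[j] @ E_acc
            f0_t, _, _, _, _ = calc.ingredients_batch(XS[[-1]])
            mem_quad = m_vec @ f0_t[0]
            assert np.max(np.abs(mem_quad - mem_impl[idx])) < 1e-6

    def test_exact_for_linear_bulk(self, linear_bulk):
        """Self-consistent reduction is exact when rates are at most linear
        in the bulk species."""
        part = linear_bulk.partition
        full = mn.integrate_full(linear_bulk, [2.0], 50.0, partition=part,
                                 bulk_at_qss=True, rtol=1e-11, atol=1e-13)
        zms = mn.integrate_zms(linear_bulk, part, [2.0], 50.0,
                               rtol=1e-11, atol=1e-13)
        ts = np.linspace(0, 50, 501)
        assert np.max(np.abs(full(ts)[:, [0]] - zms(ts))) < 1e-6

    def test_stays_at_stable_fixed_point(self, bistable2, bistable2_fps):
        x_star = bistable2_fps[2].location[[0]]
        traj = mn.integrate_zms(bistable2, bistable2.partition, x_star, 30.0)
        ts = np.linspace(0, 30, 100)
        assert np.max(np.abs(traj(ts) - x_star)) < 1e-7
        # auxiliary memory vector settles and the memory term vanishes
        mem = mn.zms_memory_series(traj, [30.0])
        assert np.max(np.abs(mem)) < 1e-9

    def test_near_fixed_point_zmn_zms_agree(self, bistable2, bistable2_fps):
        """The two memory variants share the same linearization, so small
        perturbations evolve nearly identically under both."""
        x_star = bistable2_fps[2].location[0]
        eps = 1e-3 * x_star
        x0 = [x_star + eps]
        zmn = mn.integrate_zmn(bistable2, bistable2.partition, x0, 10.0,
                               n_history=1000)
        zms = mn.integrate_zms(bistable2, bistable2.partition, x0, 10.0,
                               rtol=1e-11, atol=1e-13)
        ts = np.linspace(0, 10, 101)
        rel = np.max(np.abs(zmn(ts) - zms(ts))) / eps
        assert rel < 1e-3

    def test_relaxation_rate_matches_full_jacobian(self):
        """Slowest decay rate near a stable fixed point equals the slowest
        full-Jacobian eigenvalue (memory kernels are exact when linearized).

        Uses an asymmetric switch whose eigenvalues (-1.11, -0.39) are well
        separated, so the slow mode dominates inside the fit window while the
        deviation is still far above solver noise.
        """
        m = mn.build_model({
            "species": ["x1", "x2"],
            "rates": {"x1": "3/(1 + x2^2) - x1",
                      "x2": "2/(1 + x1^2) - 0.5*x2"},
            "params": {},
            "partition": {"sub": ["x1"], "bulk": ["x2"]},
        })
        fps = mn.find_fixed_points(m, [(0, 6)] * 2, system="full")
        fp = [f for f in fps if f.stability == "stable"][0]
        x_star = fp.location[0]
        lam_slow = np.max(np.linalg.eigvals(m.jacobian(fp.location)).real)
        traj = mn.integrate_zms(m, m.partition, [x_star * 1.001], 22.0,
                                rtol=1e-12, atol=1e-14)
        ts = np.linspace(8, 20, 100)
        dev = np.abs(traj(ts)[:, 0] - x_star)
        rate = np.polyfit(ts, np.log(dev), 1)[0]
        assert rate == pytest.approx(lam_slow, rel=0.01)

    def test_fixed_points_conserved(self, bistable2, bistable2_fps):
        """ZMs steady states coincide with the QSS-drift fixed points."""
        fps_zms = mn.find_fixed_points(bistable2, [(0, 10)], system="zms",
                                       partition=bistable2.partition)
        fps_qss = mn.find_fixed_points(bistable2, [(0, 10)], system="qss")
        a = sorted(fp.location[0] for fp in fps_zms)
        b = sorted(fp.location[0] for fp in fps_qss)
        assert np.allclose(a, b, atol=1e-8)

    def test_empty_bulk_short_circuits(self, bistable2):
        part = mn.SubnetworkPartition((0, 1), ())
        x0 = np.array([0.4, 3.0])
        zms = mn.integrate_zms(bistable2, part, x0, 5.0)
        full = mn.integrate_full(bistable2, x0, 5.0)
        ts = np.linspace(0, 5, 20)
        assert np.allclose(zms(ts), full(ts), atol=1e-9)


class TestTrajectory:
    def test_dense_matches_grid(self, bistable2):
        traj = mn.integrate_full(bistable2, [1.0, 2.0], 10.0)
        assert np.allclose(traj(traj.times), traj.states, atol=1e-12)

    def test_frame_roundtrip(self, bistable2, tmp_path):
        traj = mn.integrate_full(bistable2, [1.0, 2.0], 5.0)
        p = tmp_path / "traj.csv"
        traj.to_csv(p)
        import pandas as pd
        df = pd.read_csv(p)
        assert list(df.columns) == ["t", "x1", "x2"]
        assert len(df) == len(traj.times)

    def test_json_metadata(self, bistable2, tmp_path):
        import json
        traj = mn.integrate_full(bistable2, [1.0, 2.0], 5.0)
        p = tmp_path / "traj.json"
        traj.to_json(p)
        meta = json.loads(p.read_text())
        assert meta["variant"] == "full" and meta["t_end"] == 5.0
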