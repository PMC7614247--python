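"""Integrators for the four system variants: full, QSS, ZMn and ZMs.

All variants are launched from a shared subnetwork initial condition; the
full system's bulk is initialized at its QSS value (under which the random
force vanishes, making the projected equations a closed description).

* ``full``: the original ODE system.
* ``qss``: the memoryless reduction dx^s/dt = v(x^s).
* ``zmn``: the nonlinear projected equation with the explicit memory
  integral, dx^s/dt = v(x^s(t)) + int_0^t M(x^s(t'), t-t') dt'.  The history
  integral is discretized on a fixed grid with trapezoidal weights; each
  history node carries an auxiliary pair (QSS-flow position, propagator
  matrix) advanced in tau as t grows, so the per-step cost is linear in the
  history length.
* ``zms``: the self-consistent variant, where propagation between t' and t
  uses the actual memory-corrected trajectory.  It is evaluated through one
  auxiliary ODE per bulk species, dm/dt = c(x^s) + l(x^s)^T m, m(0) = 0,
  with memory term sum_b m_b f0_bs(x^s); it is exact when the rates depend
  at most linearly on the bulk species.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .memory_core import MemoryCalculator
from .network_model import NetworkModel, SubnetworkPartition
from .qss_reduction import QSSMap
from .trajectory import Trajectory, from_solve_ivp

__all__ = [
    "integrate_full",
    "integrate_qss",
    "integrate_zmn",
    "integrate_zms",
    "zms_memory_series",
]


def _sub_names(model, partition):
    return tuple(model.species[i] for i in partition.sub)


def integrate_full(model: NetworkModel, x0, t_end, partition=None,
                   bulk_at_qss=False, t_eval=None, rtol=1e-8, atol=1e-10,
                   method="LSODA") -> Trajectory:
    """Integrate the original full-dimensional system.

    ``x0`` is either a full state or, with ``bulk_at_qss=True`` and a
    partition, a subnetwork state whose bulk components are initialized at
    their QSS values.
    """
    x0 = np.atleast_1d(np.asarray(x0, float))
    partition = partition or model.partition
    if len(x0) != model.n_species:
        if not bulk_at_qss or partition is None:
            raise ValueError(
                "x0 has subnetwork dimension; pass bulk_at_qss=True with a partition")
        qss = QSSMap(model, partition)
        x_b = qss.solve(x0)
        full = np.empty(model.n_species)
        full[list(partition.sub)] = x0
        full[list(partition.bulk)] = x_b
        x0 = full
    sol = solve_ivp(lambda t, x: model.rates(x), (0.0, float(t_end)), x0,
                    method=method, rtol=rtol, atol=atol, dense_output=True,
                    t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"full integration failed at t = {sol.t[-1]}: {sol.message}")
    return from_solve_ivp(sol, "full", names=model.species)


def integrate_qss(model: NetworkModel, partition, xs0, t_end, t_eval=None,
                  rtol=1e-8, atol=1e-10, method="LSODA") -> Trajectory:
    """Integrate the memoryless QSS reduction dx^s/dt = v(x^s)."""
    partition = partition or model.partition
    if partition is not None and len(partition.bulk) == 0:
        traj = integrate_full(model, xs0, t_end, t_eval=t_eval, rtol=rtol,
                              atol=atol, method=method)
        traj.variant = "qss"
        return traj
    qss = QSSMap(model, partition)
    traj = qss.flow(xs0, t_end, t_eval=t_eval, rtol=rtol, atol=atol,
                    method=method)
    return traj


def integrate_zms(model: NetworkModel, partition, xs0, t_end, t_eval=None,
                  rtol=1e-8, atol=1e-10, method="LSODA",
                  calc: MemoryCalculator | None = None) -> Trajectory:
    """Integrate the self-consistent memory reduction via auxiliary ODEs.

    Augmented state (x^s, m) with m(0) = 0:
        dx^s/dt = v(x^s) + f0(x^s)^T m,
        dm/dt   = c(x^s) + l(x^s)^T m.
    The stored trajectory holds x^s; the auxiliary memory vector m and the
    memory term are available in ``aux``/via the dense augmented evaluator.
    """
    partition = partition or model.partition
    xs0 = np.atleast_1d(np.asarray(xs0, float))
    if len(partition.bulk) == 0:
        traj = integrate_full(model, xs0, t_end, t_eval=t_eval, rtol=rtol,
                              atol=atol, method=method)
        traj.variant = "zms"
        return traj
    calc = calc or MemoryCalculator(model, partition)
    ns, nb = calc.qss.n_sub, calc.qss.n_bulk
    warm = {"xb": None}

    def rhs(t, z):
        x_s, m = z[:ns], z[ns:]
        ing = calc.ingredients(x_s, guess=warm["xb"])
        warm["xb"] = ing.x_b
        return np.concatenate([ing.drift + ing.f0.T @ m, ing.c + ing.l.T @ m])

    z0 = np.concatenate([xs0, np.zeros(nb)])
    sol = solve_ivp(rhs, (0.0, float(t_end)), z0, method=method, rtol=rtol,
                    atol=atol, dense_output=True, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"ZMs integration failed at t = {sol.t[-1]}: {sol.message}")
    times = np.asarray(sol.t)
    Z = np.asarray(sol.y).T
    dense_aug = sol.sol

    def dense(t):
        out = np.asarray(dense_aug(t))
        return out[:ns]

    return Trajectory(times, Z[:, :ns], "zms", dense=dense,
                      names=_sub_names(model, partition),
                      aux={"m": Z[:, ns:], "dense_augmented": dense_aug,
                           "calc": calc})


def zms_memory_series(traj: Trajectory, times) -> np.ndarray:
    """Memory term sum_b m_b(t) f0_bs(x^s(t)) along a ZMs trajectory."""
    calc: MemoryCalculator = traj.aux["calc"]
    ns = calc.qss.n_sub
    Z = np.asarray(traj.aux["dense_augmented"](np.asarray(times, float)))
    XS, M = Z[:ns].T, Z[ns:].T
    f0, _, _, _, _ = calc.ingredients_batch(XS)
    return np.einsum("tb,tbs->ts", M, f0)


# --------------------------------------------------------------------------
# ZMn: explicit history integral
# --------------------------------------------------------------------------

def integrate_zmn(model: NetworkModel, partition, xs0, t_end,
                  n_history: int = 2000, prune_tol: float = 1e-12,
                  calc: MemoryCalculator | None = None) -> Trajectory:
    """Integrate the nonlinear projected equation with explicit memory.

    Fixed-step Heun (trapezoidal predictor-corrector) outer scheme on the
    history grid with step h = t_end/n_history; the memory integral uses
    trapezoidal weights over the history nodes.  Each node j holds the frozen
    prefactor c(x^s(t_j)) plus an auxiliary pair (y_j, E_j) = (QSS-flow
    position, time-ordered propagator) advanced jointly by one vectorized RK4
    step per outer step.  Nodes whose propagator norm has decayed below
    ``prune_tol`` (relative to ||E(0)|| = sqrt(n_bulk)) stop contributing.
    Overall accuracy is O(h^2), dominated by the trapezoidal history rule.
    """
    partition = partition or model.partition
    xs0 = np.atleast_1d(np.asarray(xs0, float))
    if len(partition.bulk) == 0:
        traj = integrate_full(model, xs0, t_end)
        traj.variant = "zmn"
        return traj
    calc = calc or MemoryCalculator(model, partition)
    qss = calc.qss
    ns, nb = qss.n_sub, qss.n_bulk
    h = float(t_end) / int(n_history)
    n_steps = int(n_history)

    def batch_ing(Y, XB_guess):
        f0, l, c, Rs, XB = calc.ingredients_batch(Y, guess=XB_guess)
        return f0, l, Rs, XB

    def aux_derivs(Y, E, XB_guess):
        """d/dtau of the node auxiliaries: y' = v(y), E' = E l(y)."""
        f0, l, Rs, XB = batch_ing(Y, XB_guess)
        return Rs, np.einsum("jab,jbc->jac", E, l), XB

    def memory_sum(C, E, Y, XB_guess, active):
        """Trapezoid of M_j = c_j E_j f0(y_j) over active history nodes."""
        k = len(C) - 1
        if k == 0:
            return np.zeros(ns), XB_guess
        idx = np.flatnonzero(active)
        f0, _, _, XB_new = batch_ing(Y[idx], XB_guess[idx])
        Mj = np.einsum("jb,jbc,jcs->js", C[idx], E[idx], f0)
        w = np.full(len(C), h)
        w[0] = w[-1] = 0.5 * h
        XB_out = XB_guess.copy()
        XB_out[idx] = XB_new
        return w[idx] @ Mj, XB_out

    # node state arrays, grown as the history accumulates
    X = np.empty((n_steps + 1, ns))
    X[0] = xs0
    ing0 = calc.ingredients(xs0)
    C = [ing0.c]
    Y = np.array([xs0])
    E = np.tile(np.eye(nb), (1, 1, 1))
    XB = np.array([ing0.x_b])
    active = np.array([True])
    scaleE = np.sqrt(nb)

    for k in range(n_steps):
        x = X[k]
        mem_k, XB = memory_sum(np.array(C), E, Y, XB, active)
        drift_k = calc.ingredients(x, guess=XB[-1]).drift
        f1 = drift_k + mem_k

        # advance node auxiliaries tau -> tau + h with one RK4 step
        idx = np.flatnonzero(active)
        Ya, Ea, XBa = Y[idx], E[idx], XB[idx]
        k1y, k1e, XBa = aux_derivs(Ya, Ea, XBa)
        k2y, k2e, XBa = aux_derivs(Ya + 0.5 * h * k1y, Ea + 0.5 * h * k1e, XBa)
        k3y, k3e, XBa = aux_derivs(Ya + 0.5 * h * k2y, Ea + 0.5 * h * k2e, XBa)
        k4y, k4e, XBa = aux_derivs(Ya + h * k3y, Ea + h * k3e, XBa)
        Y[idx] = Ya + (h / 6) * (k1y + 2 * k2y + 2 * k3y + k4y)
        E[idx] = Ea + (h / 6) * (k1e + 2 * k2e + 2 * k3e + k4e)
        XB[idx] = XBa
        norms = np.linalg.norm(E[idx].reshape(len(idx), -1), axis=1)
        active[idx] &= norms >= prune_tol * scaleE

        # predictor, then corrector with the memory re-evaluated at t_{k+1}
        x_pred = x + h * f1
        ing_p = calc.ingredients(x_pred, guess=XB[-1])
        C.append(ing_p.c)
        Y = np.vstack([Y, x_pred[None]])
        E = np.concatenate([E, np.eye(nb)[None]], axis=0)
        XB = np.vstack([XB, ing_p.x_b[None]])
        active = np.append(active, True)
        mem_p, XB = memory_sum(np.array(C), E, Y, XB, active)
        f2 = ing_p.drift + mem_p
        X[k + 1] = x + 0.5 * h * (f1 + f2)

        # refresh the newest node with the corrected state
        ing_c = calc.ingredients(X[k + 1], guess=XB[-1])
        C[-1] = ing_c.c
        Y[-1] = X[k + 1]
        XB[-1] = ing_c.x_b

    times = h * np.arange(n_steps + 1)
    times[0] = 0.0
    spline = CubicSpline(times, X, axis=0)
    return Trajectory(times, X, "zmn", dense=lambda t: spline(t).T,
                      names=_sub_names(model, partition))
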