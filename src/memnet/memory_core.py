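"""Closed-form nonlinear memory functions for the subnetwork reduction.

For a network partitioned into subnetwork and bulk, the projected subnetwork
equation is

    dx^s/dt = v(x^s(t)) + \\int_0^t dt' M(x^s(t'), t - t'),

where v is the QSS drift and the memory function has the closed form

    M_s(x^s, tau) = sum_{b'} c_{b'}(x^s) f_{b's}(x^s, tau),
    f_{bs}(x^s, tau) = sum_{b'} E_{bb'}(tau) f0_{b's}(phi_v(x^s, tau)),

with the x^s-dependent ingredients (all derivatives at (x^s, x^b*(x^s))):

    f0_{bs}   = dR_s/dx_b,
    J_{b''b'} = dR_{b''}/dx_{b'}                      (bulk Jacobian),
    l_{bb'}   = J_{b'b} + sum_{s'b''} (J^-1)_{b'b''} dR_{b''}/dx_{s'} dR_{s'}/dx_b,
    c_{b'}    = sum_{s'b''} (J^-1)_{b'b''} dR_{b''}/dx_{s'} R_{s'},

and E(tau) the time-ordered exponential of l along the QSS flow.  The
ordering convention (new generator multiplying from the right as tau grows,
dE/dtau = E l(phi_v(x^s, tau))) is the one under which the reduction is
exact for bulk-linear rates; it is certified end-to-end by the linear-bulk
exactness and linearized-kernel tests rather than fixed by notation.

Because c carries a factor of the QSS drift, the memory vanishes identically
at every fixed point of the reduced dynamics; near a stable fixed point the
memory linearizes to a time convolution with the kernel produced by
:meth:`MemoryCalculator.linearized_kernel`, which reproduces the full
linearized dynamics exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .network_model import NetworkModel, SubnetworkPartition
from .qss_reduction import QSSMap

__all__ = [
    "MemoryIngredients",
    "MemoryEvaluation",
    "LinearKernel",
    "MemoryCalculator",
    "memory_ingredients",
    "memory_function",
    "propagator",
    "linearized_kernel",
    "random_force",
]


@dataclass
class MemoryIngredients:
    """The x^s-dependent objects entering every memory formula.

    Index conventions: ``f0`` is (bulk, subnetwork) with f0[b, s] = dR_s/dx_b;
    ``l`` is (bulk, bulk); ``c`` is bulk-indexed; ``J`` is the bulk-bulk
    Jacobian block; ``W = J^-1 dR^b/dx^s`` (bulk, subnetwork) is the shared
    contraction appearing in both l and c; ``drift`` is the QSS drift v(x^s).
    """

    x_s: np.ndarray
    x_b: np.ndarray
    f0: np.ndarray
    l: np.ndarray
    c: np.ndarray
    J: np.ndarray
    W: np.ndarray
    A_ss: np.ndarray
    drift: np.ndarray


@dataclass
class MemoryEvaluation:
    """Memory function values M_s(x^s, tau) on a tau grid, with the
    transported points phi_v(x^s, tau) and propagators E(tau)."""

    x_s: np.ndarray
    tau: np.ndarray
    M: np.ndarray          # shape (len(tau), n_sub)
    transported: np.ndarray  # phi_v(x^s, tau), shape (len(tau), n_sub)
    E: np.ndarray          # shape (len(tau), n_bulk, n_bulk)

    def to_frame(self, names=None):
        """Tabulate as CSV-ready rows: x^s coordinates, tau, M per species
        (supports regenerating memory heatmaps over (x^s, tau))."""
        import pandas as pd

        ns = len(self.x_s)
        cols = list(names) if names else [f"x{i+1}" for i in range(ns)]
        data = {c: np.full(len(self.tau), v)
                for c, v in zip(cols, self.x_s)}
        data["tau"] = self.tau
        for k in range(self.M.shape[1]):
            data[f"M_{cols[k] if k < ns else k}"] = self.M[:, k]
        return pd.DataFrame(data)


@dataclass
class LinearKernel:
    """Convolution kernel K(tau) of the memory linearized at a fixed point.

    The linearized projected dynamics read
    d dx^s/dt = Dv dx^s + \\int_0^t K(t - t') dx^s(t') dt' with
    K(tau) = f0*^T exp(l*^T tau) G and G = J^-1 (dR^b/dx^s) Dv, all factors
    frozen at the fixed point (only the drift factor inside c, which vanishes
    there, is differentiated).  The kernels of the ZMn and ZMs variants
    coincide in this linearization.
    """

    x_s_star: np.ndarray
    x_b_star: np.ndarray
    l_star: np.ndarray
    f0_star: np.ndarray
    G: np.ndarray
    drift_jacobian: np.ndarray

    def __call__(self, tau: float) -> np.ndarray:
        if self.l_star.size == 0:
            ns = self.f0_star.shape[1]
            return np.zeros((ns, ns))
        return self.f0_star.T @ expm(self.l_star.T * float(tau)) @ self.G


class MemoryCalculator:
    """Evaluates memory ingredients, propagators and memory functions for one
    model/partition pair, with light memoization keyed on x^s."""

    def __init__(self, model: NetworkModel,
                 partition: SubnetworkPartition | None = None,
                 qss: QSSMap | None = None,
                 rtol: float = 1e-10, atol: float = 1e-12):
        self.model = model
        self.qss = qss or QSSMap(model, partition)
        self.partition = self.qss.partition
        self.rtol = rtol
        self.atol = atol
        self._cache: dict[tuple, MemoryIngredients] = {}

    # ----------------------------------------------------------- ingredients
    def ingredients(self, x_s, guess=None) -> MemoryIngredients:
        # copy: callers may pass views into solver state that mutate later
        x_s = np.array(x_s, float, ndmin=1)
        key = tuple(np.round(x_s, 12))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        A_ss, A_sb, A_bs, J, x_b, Rs = self.qss.blocks(x_s, guess=guess)
        nb, ns = len(x_b), len(x_s)
        if nb == 0:
            ing = MemoryIngredients(x_s, x_b, np.zeros((0, ns)), np.zeros((0, 0)),
                                    np.zeros(0), J, np.zeros((0, ns)), A_ss, Rs)
        else:
            try:
                W = np.linalg.solve(J, A_bs)          # W[b', s'] = (J^-1 dR^b/dx^s)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"singular bulk Jacobian at x^s = {x_s}") from exc
            f0 = A_sb.T                                # f0[b, s] = dR_s/dx_b
            l = J.T + f0 @ W.T                         # l[b, b'] per the memory PDE
            c = W @ Rs                                 # c[b'] = sum_s' W[b',s'] R_s'
            ing = MemoryIngredients(x_s, x_b, f0, l, c, J, W, A_ss, Rs)
        if len(self._cache) > 4096:
            self._cache.clear()
        self._cache[key] = ing
        return ing

    def ingredients_batch(self, XS: np.ndarray, guess=None):
        """Vectorized (f0, l, c, drift, x_b) for a batch of subnetwork states."""
        XS = np.atleast_2d(np.asarray(XS, float))
        m = XS.shape[0]
        q = self.qss
        XB = q.solve_batch(XS, guess=guess)
        full = np.empty((m, self.model.n_species))
        full[:, q._sub] = XS
        if q.n_bulk:
            full[:, q._bulk] = XB
        R = self.model.rates_batch(full)
        A = self.model.jacobian_batch(full)
        sub, blk = q._sub, q._bulk
        A_sb = A[:, sub][:, :, blk]
        A_bs = A[:, blk][:, :, sub]
        J = A[:, blk][:, :, blk]
        f0 = np.swapaxes(A_sb, 1, 2)
        W = np.linalg.solve(J, A_bs)
        l = np.swapaxes(J, 1, 2) + np.einsum("mbs,mcs->mbc", f0, W)
        Rs = R[:, sub]
        c = np.einsum("mbs,ms->mb", W, Rs)
        return f0, l, c, Rs, XB

    # ------------------------------------------------------------ propagator
    def flow_and_propagator(self, x_s, tau_max, dense=True):
        """Jointly integrate y' = v(y), E' = E l(y) from (x_s, I).

        Returns the solve_ivp solution over [0, tau_max] whose state is
        [y (n_sub), E.ravel() (n_bulk^2)].
        """
        x_s = np.atleast_1d(np.asarray(x_s, float))
        ns, nb = self.qss.n_sub, self.qss.n_bulk
        warm = {"xb": None}

        def rhs(t, z):
            y = z[:ns]
            ing = self.ingredients(y, guess=warm["xb"])
            warm["xb"] = ing.x_b
            E = z[ns:].reshape(nb, nb)
            return np.concatenate([ing.drift, (E @ ing.l).ravel()])

        z0 = np.concatenate([x_s, np.eye(nb).ravel()])
        sol = solve_ivp(rhs, (0.0, float(tau_max)), z0, method="LSODA",
                        rtol=self.rtol, atol=self.atol, dense_output=dense)
        if not sol.success:
            raise RuntimeError(f"propagator integration failed: {sol.message}")
        return sol

    def propagator(self, x_s, tau) -> np.ndarray:
        """Time-ordered matrix exponential E(tau) of l along the QSS flow.

        E(0) = I; for scalar bulk this reduces to
        exp(int_0^tau l(phi_v(x^s, tau')) dtau').
        """
        ns, nb = self.qss.n_sub, self.qss.n_bulk
        tau = np.asarray(tau, float)
        scalar = tau.ndim == 0
        taus = np.atleast_1d(tau)
        if np.any(taus < 0):
            raise ValueError("tau must be nonnegative")
        if nb == 0:
            E = np.zeros((len(taus), 0, 0))
            return E[0] if scalar else E
        if taus.max() == 0.0:
            E = np.tile(np.eye(nb), (len(taus), 1, 1))
            return E[0] if scalar else E
        sol = self.flow_and_propagator(x_s, taus.max())
        Z = sol.sol(taus)
        E = Z[ns:].T.reshape(len(taus), nb, nb)
        return E[0] if scalar else E

    # ---------------------------------------------------------------- memory
    def memory(self, x_s, tau) -> MemoryEvaluation:
        """Evaluate M_s(x^s, tau) on a tau grid (scalar tau allowed)."""
        x_s = np.atleast_1d(np.asarray(x_s, float))
        taus = np.atleast_1d(np.asarray(tau, float))
        ns, nb = self.qss.n_sub, self.qss.n_bulk
        if nb == 0:
            zeros = np.zeros((len(taus), ns))
            return MemoryEvaluation(x_s, taus, zeros,
                                    np.tile(x_s, (len(taus), 1)),
                                    np.zeros((len(taus), 0, 0)))
        if taus.max() == 0.0:
            Y = np.tile(x_s, (len(taus), 1))
            E = np.tile(np.eye(nb), (len(taus), 1, 1))
        else:
            sol = self.flow_and_propagator(x_s, taus.max())
            Z = sol.sol(taus)
            Y = Z[:ns].T
            E = Z[ns:].T.reshape(len(taus), nb, nb)
        f0_y, _, _, _, _ = self.ingredients_batch(Y)
        c = self.ingredients(x_s).c
        M = np.einsum("b,tbc,tcs->ts", c, E, f0_y)
        return MemoryEvaluation(x_s, taus, M, Y, E)

    def memory_amplitude(self, x_s) -> np.ndarray:
        """Zero-delay memory M(x^s, 0) = sum_b c_b(x^s) f0_bs(x^s)."""
        ing = self.ingredients(np.atleast_1d(np.asarray(x_s, float)))
        if self.qss.n_bulk == 0:
            return np.zeros(self.qss.n_sub)
        return ing.c @ ing.f0

    # ----------------------------------------------------- linearized kernel
    def linearized_kernel(self, x_s_star, residual_tol=1e-8) -> LinearKernel:
        """Memory kernel of the dynamics linearized at a QSS-drift fixed point."""
        x_s_star = np.atleast_1d(np.asarray(x_s_star, float))
        ing = self.ingredients(x_s_star)
        if np.max(np.abs(ing.drift), initial=0.0) > residual_tol:
            raise ValueError(
                f"{x_s_star} is not a fixed point of the QSS drift "
                f"(|v| = {np.max(np.abs(ing.drift)):.2e})")
        if self.qss.n_bulk == 0:
            Dv = ing.A_ss
            G = np.zeros((0, self.qss.n_sub))
        else:
            Dv = ing.A_ss - ing.f0.T @ ing.W
            G = ing.W @ Dv
        return LinearKernel(x_s_star, ing.x_b, ing.l, ing.f0, G, Dv)

    # ----------------------------------------------------------- random force
    def random_force(self, x_s, x_b, tau) -> np.ndarray:
        """Closed-form random-force approximation
        F_s(x^s, x^b, tau) = sum_b (x_b - x_b*(x^s)) f_bs(x^s, tau).

        Captures the leading effect of the bulk starting away from QSS; it
        vanishes identically when x^b(0) = x^b*(x^s).  Returns shape
        (len(tau), n_sub) (or (n_sub,) for scalar tau).
        """
        x_b = np.atleast_1d(np.asarray(x_b, float))
        ev = self.memory(x_s, tau)
        if self.qss.n_bulk == 0:
            return ev.M * 0.0
        dev = x_b - self.ingredients(ev.x_s).x_b
        f0_y, _, _, _, _ = self.ingredients_batch(ev.transported)
        f = np.einsum("tbc,tcs->tbs", ev.E, f0_y)   # f_{bs}(x^s, tau)
        F = np.einsum("b,tbs->ts", dev, f)
        return F[0] if np.asarray(tau).ndim == 0 else F


# --------------------------------------------------------------------------
# Module-level convenience wrappers
# --------------------------------------------------------------------------

def memory_ingredients(model, partition, x_s) -> MemoryIngredients:
    return MemoryCalculator(model, partition).ingredients(x_s)


def propagator(model, partition, x_s, tau) -> np.ndarray:
    return MemoryCalculator(model, partition).propagator(x_s, tau)


def memory_function(model, partition, x_s, tau) -> MemoryEvaluation:
    return MemoryCalculator(model, partition).memory(x_s, tau)


def linearized_kernel(model, partition, fixed_point) -> LinearKernel:
    return MemoryCalculator(model, partition).linearized_kernel(fixed_point)


def random_force(model, partition, x_s, x_b, tau) -> np.ndarray:
    return MemoryCalculator(model, partition).random_force(x_s, x_b, tau)
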