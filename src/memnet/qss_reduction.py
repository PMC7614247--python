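"""Quasi-steady-state reduction: bulk QSS solve, QSS drift/flow, fixed points.

For a partitioned network dx^s/dt = R^s(x^s, x^b), dx^b/dt = R^b(x^s, x^b),
the bulk QSS x^b*(x^s) solves R^b(x^s, x^b*) = 0 and is assumed unique for
every subnetwork state (the method's one structural precondition; violations
are detected by deterministic multi-start).  The QSS drift
v(x^s) = R^s(x^s, x^b*(x^s)) is the memoryless baseline reduction; its flow
phi_v transports subnetwork states and underlies every memory formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.stats import qmc

from .network_model import NetworkModel, SubnetworkPartition
from .trajectory import Trajectory, from_solve_ivp

__all__ = [
    "QSSMap",
    "FixedPoint",
    "QSSError",
    "UniquenessViolationError",
    "find_fixed_points",
    "fixed_points_to_frame",
]


class QSSError(RuntimeError):
    """Bulk QSS solve failed to converge."""


class UniquenessViolationError(QSSError):
    """Multi-start found more than one bulk steady state for one x^s."""


@dataclass
class FixedPoint:
    """A fixed point with its Jacobian spectrum and stability label.

    ``system`` records which dynamics it belongs to (full | qss | zms); for
    the reduced systems the location is the subnetwork state.
    """

    location: np.ndarray
    eigenvalues: np.ndarray
    stability: str  # stable | saddle | unstable | marginal
    system: str

    @property
    def leading_eigenvalue(self) -> complex:
        return self.eigenvalues[np.argmax(self.eigenvalues.real)]


def classify_eigenvalues(eig: np.ndarray, marginal_tol: float = 1e-8) -> str:
    re = np.real(eig)
    if np.any(np.abs(re) < marginal_tol):
        return "marginal"
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


class QSSMap:
    """Solver for the bulk quasi-steady state and the QSS drift/flow.

    Newton iteration with analytic bulk Jacobian; warm-started from the last
    solution for continuation along trajectories.  Without a guess, a
    deterministic multi-start (cached solution, origin, and ``n_multistart``
    Halton points in a production/degradation box) detects violations of the
    bulk-uniqueness precondition.
    """

    def __init__(
        self,
        model: NetworkModel,
        partition: SubnetworkPartition | None = None,
        tol: float = 1e-10,
        max_iter: int = 100,
        n_multistart: int = 8,
    ):
        self.model = model
        self.partition = partition or model.partition
        if self.partition is None:
            raise ValueError("no partition given and model has no default")
        self.partition.validate_for(model)
        self.tol = tol
        self.max_iter = max_iter
        self.n_multistart = n_multistart
        self._cache_xb: np.ndarray | None = None
        self.last_condition_number: float | None = None
        p = self.partition
        self._sub = np.array(p.sub, int)
        self._bulk = np.array(p.bulk, int)
        self._bb = np.ix_(self._bulk, self._bulk)
        self._setup_affine_bulk()

    def _setup_affine_bulk(self) -> None:
        """Fast path: if every bulk rate is affine in the bulk species,
        R^b = D(x^s) x^b + g(x^s), the QSS is a single linear solve and the
        bulk steady state is automatically unique (for invertible D)."""
        import sympy as sp

        model = self.model
        bulk_syms = [model._sym[model.species[b]] for b in self._bulk]
        sub_syms = [model._sym[model.species[s]] for s in self._sub]
        self._affine = False
        if self.n_bulk == 0:
            return
        D = []
        for b in self._bulk:
            row = []
            for bs in bulk_syms:
                d = sp.diff(model._exprs[b], bs)
                if d.free_symbols & set(bulk_syms):
                    return  # not affine in the bulk
                row.append(d)
            D.append(row)
        zero_bulk = {bs: sp.Integer(0) for bs in bulk_syms}
        g = [model._exprs[b].xreplace(zero_bulk) for b in self._bulk]
        self._affine = True
        self._D_fn = sp.lambdify(sub_syms, D, modules="numpy")
        self._g_fn = sp.lambdify(sub_syms, g, modules="numpy")

    # ------------------------------------------------------------ utilities
    @property
    def n_sub(self) -> int:
        return len(self._sub)

    @property
    def n_bulk(self) -> int:
        return len(self._bulk)

    def _full_state(self, x_s, x_b):
        x = np.empty(self.model.n_species)
        x[self._sub] = x_s
        if self.n_bulk:
            x[self._bulk] = x_b
        return x

    def _bulk_residual(self, x_s, x_b):
        return self.model.rates(self._full_state(x_s, x_b))[self._bulk]

    def _bulk_jacobian(self, x_s, x_b):
        J = self.model.jacobian(self._full_state(x_s, x_b))
        return J[self._bb]

    def _solve_affine(self, x_s) -> np.ndarray:
        D = np.asarray(self._D_fn(*x_s), float)
        g = np.asarray(self._g_fn(*x_s), float)
        try:
            return np.linalg.solve(D, -g)
        except np.linalg.LinAlgError as exc:
            raise QSSError(f"singular bulk matrix at x^s = {x_s}") from exc

    def _start_box(self, x_s) -> np.ndarray:
        """Per-bulk-species upper bound from production/degradation balance."""
        hi = np.empty(self.n_bulk)
        x0 = self._full_state(np.asarray(x_s, float), np.zeros(self.n_bulk))
        R0 = self.model.rates(x0)
        J0 = self.model.jacobian(x0)
        for k, b in enumerate(self._bulk):
            prod = max(R0[b], 0.0)
            degr = max(-J0[b, b], 0.1)
            hi[k] = max(1.0, 4.0 * prod / degr)
        return hi

    # --------------------------------------------------------------- solves
    def _newton(self, x_s, x_b0) -> np.ndarray | None:
        x_b = np.asarray(x_b0, float).copy()
        f = self._bulk_residual(x_s, x_b)
        for _ in range(self.max_iter):
            nf = np.max(np.abs(f))
            if nf <= self.tol:
                return x_b
            J = self._bulk_jacobian(x_s, x_b)
            try:
                step = np.linalg.solve(J, f)
            except np.linalg.LinAlgError:
                return None
            lam = 1.0
            for _ in range(40):  # backtracking on the residual norm
                x_new = x_b - lam * step
                try:
                    f_new = self._bulk_residual(x_s, x_new)
                except Exception:
                    f_new = np.array([np.inf])
                if np.all(np.isfinite(f_new)) and np.max(np.abs(f_new)) < nf:
                    x_b, f = x_new, f_new
                    break
                lam *= 0.5
            else:
                return None
        return x_b if np.max(np.abs(f)) <= self.tol else None

    def solve(self, x_s, guess=None) -> np.ndarray:
        """Solve R^b(x^s, x^b) = 0 for x^b*(x^s).

        With a guess (or a cached previous solution) a single warm-started
        Newton run is used; otherwise deterministic multi-start screens for
        uniqueness violations.
        """
        x_s = np.atleast_1d(np.asarray(x_s, float))
        if self.n_bulk == 0:
            return np.empty(0)
        if self._affine:
            sol = self._solve_affine(x_s)
        elif guess is not None:
            sol = self._newton(x_s, guess)
            if sol is None:
                sol = self._multistart(x_s)
        elif self._cache_xb is not None:
            sol = self._newton(x_s, self._cache_xb)
            if sol is None:
                sol = self._multistart(x_s)
        else:
            sol = self._multistart(x_s)
        self._cache_xb = sol.copy()
        return sol

    def condition_number(self, x_s) -> float:
        """Condition number of the bulk Jacobian at (x^s, x^b*(x^s))."""
        x_s = np.atleast_1d(np.asarray(x_s, float))
        J = self._bulk_jacobian(x_s, self.solve(x_s))
        cond = float(np.linalg.cond(J))
        self.last_condition_number = cond
        return cond

    def _multistart(self, x_s) -> np.ndarray:
        starts = [np.zeros(self.n_bulk)]
        if self._cache_xb is not None:
            starts.insert(0, self._cache_xb)
        hi = self._start_box(x_s)
        if self.n_multistart > 0:
            h = qmc.Halton(d=self.n_bulk, scramble=False)
            h.fast_forward(1)  # skip the origin-duplicate first point
            starts.extend(h.random(self.n_multistart) * hi)
        roots: list[np.ndarray] = []
        for x_b0 in starts:
            sol = self._newton(x_s, x_b0)
            if sol is None:
                continue
            if not any(np.max(np.abs(sol - r)) < 1e-6 for r in roots):
                roots.append(sol)
        if not roots:
            raise QSSError(f"bulk QSS solve failed at x^s = {x_s}")
        if len(roots) > 1:
            raise UniquenessViolationError(
                f"multiple bulk steady states at x^s = {x_s}: {roots}; "
                "the unique-bulk-QSS precondition is violated"
            )
        return roots[0]

    def solve_batch(self, XS: np.ndarray, guess: np.ndarray | None = None) -> np.ndarray:
        """Vectorized warm-started Newton for many subnetwork states at once."""
        XS = np.atleast_2d(np.asarray(XS, float))
        m = XS.shape[0]
        nb = self.n_bulk
        if nb == 0:
            return np.empty((m, 0))
        if self._affine:
            cols = [XS[:, j] for j in range(XS.shape[1])]
            Drows = self._D_fn(*cols)
            grows = self._g_fn(*cols)
            D = np.empty((m, nb, nb))
            g = np.empty((m, nb))
            for i in range(nb):
                g[:, i] = grows[i]
                for j in range(nb):
                    D[:, i, j] = Drows[i][j]
            return np.linalg.solve(D, -g[..., None])[..., 0]
        if guess is None:
            xb0 = self._cache_xb if self._cache_xb is not None else np.zeros(nb)
            XB = np.tile(xb0, (m, 1))
        else:
            XB = np.array(guess, float, copy=True)
            if XB.ndim == 1:
                XB = np.tile(XB, (m, 1))
        full = np.empty((m, self.model.n_species))
        full[:, self._sub] = XS
        active = np.ones(m, bool)
        for _ in range(self.max_iter):
            full[:, self._bulk] = XB
            F = self.model.rates_batch(full[active])[:, self._bulk]
            conv = np.max(np.abs(F), axis=1) <= self.tol
            if conv.all():
                active[np.flatnonzero(active)] = False
                break
            idx = np.flatnonzero(active)[~conv]
            sub_full = np.empty((len(idx), self.model.n_species))
            sub_full[:, self._sub] = XS[idx]
            sub_full[:, self._bulk] = XB[idx]
            J = self.model.jacobian_batch(sub_full)[:, self._bulk][:, :, self._bulk]
            step = np.linalg.solve(J, F[~conv][..., None])[..., 0]
            XB[idx] -= step
            active[np.flatnonzero(active)[conv]] = False
            if not active.any():
                break
        # final residual check (one per-sample fallback for stragglers)
        full[:, self._bulk] = XB
        F = self.model.rates_batch(full)[:, self._bulk]
        bad = np.max(np.abs(F), axis=1) > self.tol
        for i in np.flatnonzero(bad):
            XB[i] = self.solve(XS[i], guess=XB[i])
        return XB

    # ---------------------------------------------------------------- drift
    def drift(self, x_s, guess=None) -> np.ndarray:
        """QSS drift v(x^s) = R^s(x^s, x^b*(x^s))."""
        x_s = np.atleast_1d(np.asarray(x_s, float))
        x_b = self.solve(x_s, guess=guess)
        return self.model.rates(self._full_state(x_s, x_b))[self._sub]

    def drift_batch(self, XS: np.ndarray, guess=None) -> tuple[np.ndarray, np.ndarray]:
        XS = np.atleast_2d(np.asarray(XS, float))
        XB = self.solve_batch(XS, guess=guess)
        full = np.empty((XS.shape[0], self.model.n_species))
        full[:, self._sub] = XS
        if self.n_bulk:
            full[:, self._bulk] = XB
        return self.model.rates_batch(full)[:, self._sub], XB

    def blocks(self, x_s, guess=None):
        """Jacobian blocks and drift at (x^s, x^b*(x^s)).

        Returns (A_ss, A_sb, A_bs, J, x_b, drift) where J is the bulk-bulk
        Jacobian block dR_b''/dx_b'.
        """
        x_s = np.atleast_1d(np.asarray(x_s, float))
        x_b = self.solve(x_s, guess=guess)
        full = self._full_state(x_s, x_b)
        A = self.model.jacobian(full)
        R = self.model.rates(full)
        return (
            A[np.ix_(self._sub, self._sub)],
            A[np.ix_(self._sub, self._bulk)],
            A[np.ix_(self._bulk, self._sub)],
            A[np.ix_(self._bulk, self._bulk)],
            x_b,
            R[self._sub],
        )

    def drift_jacobian(self, x_s) -> np.ndarray:
        """Total derivative of the QSS drift, dv/dx^s."""
        A_ss, A_sb, A_bs, J, _, _ = self.blocks(x_s)
        if self.n_bulk == 0:
            return A_ss
        return A_ss - A_sb @ np.linalg.solve(J, A_bs)

    # ----------------------------------------------------------------- flow
    def flow(self, x_s0, t_end, t_eval=None, rtol=1e-9, atol=1e-12,
             method="LSODA") -> Trajectory:
        """Integrate the QSS drift from x^s(0) = x_s0; dense output."""
        x_s0 = np.atleast_1d(np.asarray(x_s0, float))
        qss_guess = {"xb": None}

        def rhs(t, x):
            v = self.drift(x, guess=qss_guess["xb"])
            qss_guess["xb"] = self._cache_xb
            return v

        sol = solve_ivp(rhs, (0.0, float(t_end)), x_s0, method=method,
                        rtol=rtol, atol=atol, dense_output=True, t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(
                f"QSS flow integration failed at t = {sol.t[-1]}: {sol.message}")
        names = tuple(self.model.species[i] for i in self._sub)
        return from_solve_ivp(sol, "qss", names=names)


# --------------------------------------------------------------------------
# Fixed-point location and classification
# --------------------------------------------------------------------------

def _zms_system(model, partition):
    from .memory_core import MemoryCalculator  # local import avoids a cycle

    calc = MemoryCalculator(model, partition)
    ns, nb = calc.qss.n_sub, calc.qss.n_bulk

    def rhs(z):
        x_s, m = z[:ns], z[ns:]
        ing = calc.ingredients(x_s)
        return np.concatenate([ing.drift + ing.f0.T @ m, ing.c + ing.l.T @ m])

    return rhs, ns + nb, ns


def find_fixed_points(
    model: NetworkModel,
    box,
    system: str = "full",
    partition: SubnetworkPartition | None = None,
    n_starts: int = 64,
    residual_tol: float = 1e-9,
    merge_tol: float = 1e-6,
    marginal_tol: float = 1e-8,
) -> list[FixedPoint]:
    """Locate and classify fixed points of the full, QSS, or ZMs dynamics.

    Roots are searched from a deterministic Halton start grid inside ``box``
    (sequence of (lo, hi) pairs, one per coordinate of the chosen system's
    state: full dimension for ``full``, subnetwork dimension for ``qss`` and
    ``zms``), merged at ``merge_tol`` and classified by Jacobian eigenvalues.
    Eigenvalues with |Re| below ``marginal_tol`` yield the label ``marginal``
    rather than a silent stability call.
    """
    box = np.asarray(box, float)
    if system == "full":
        dim = model.n_species
        fun = model.rates
        jac = model.jacobian
    elif system == "qss":
        qss = QSSMap(model, partition)
        dim = qss.n_sub
        fun = lambda x: qss.drift(x)
        jac = qss.drift_jacobian
    elif system == "zms":
        rhs, aug_dim, ns = _zms_system(model, partition or model.partition)
        dim = ns
        fd_h = 1e-6

        def fun(x):
            return rhs(np.concatenate([x, np.zeros(aug_dim - ns)]))[:ns]

        def jac(x):  # FD Jacobian of the augmented system at m = m* = 0
            z0 = np.concatenate([x, np.zeros(aug_dim - ns)])
            J = np.empty((aug_dim, aug_dim))
            for j in range(aug_dim):
                zp, zm = z0.copy(), z0.copy()
                zp[j] += fd_h
                zm[j] -= fd_h
                J[:, j] = (rhs(zp) - rhs(zm)) / (2 * fd_h)
            return J
    else:
        raise ValueError(f"unknown system {system!r}")
    if box.shape != (dim, 2):
        raise ValueError(f"box must have shape ({dim}, 2) for system {system!r}")

    sampler = qmc.Halton(d=dim, scramble=False)
    starts = qmc.scale(sampler.random(max(1, n_starts)), box[:, 0], box[:, 1])

    roots: list[np.ndarray] = []
    for x0 in starts:
        try:
            sol = root(fun, x0, method="hybr", tol=1e-12)
        except Exception:
            continue
        if not sol.success:
            continue
        x = sol.x
        try:
            res = np.max(np.abs(fun(x)))
        except Exception:
            continue
        if res > residual_tol:
            continue
        if np.any(x < box[:, 0] - 1e-6) or np.any(x > box[:, 1] + 1e-6):
            continue
        if not any(np.max(np.abs(x - r)) < merge_tol for r in roots):
            roots.append(x)

    out = []
    for x in sorted(roots, key=lambda r: tuple(np.round(r, 9))):
        eig = np.linalg.eigvals(jac(x))
        out.append(FixedPoint(x, eig, classify_eigenvalues(eig, marginal_tol), system))
    return out


def fixed_points_to_frame(fps: list[FixedPoint], names=None) -> pd.DataFrame:
    """Tabulate fixed points (CSV-ready): system, coordinates, stability,
    leading eigenvalue real/imag."""
    rows = []
    for fp in fps:
        lead = fp.leading_eigenvalue
        row = {"system": fp.system}
        cols = names or [f"x{i+1}" for i in range(len(fp.location))]
        row.update({c: v for c, v in zip(cols, fp.location)})
        row["stability"] = fp.stability
        row["re_lambda"] = float(np.real(lead))
        row["im_lambda"] = float(np.imag(lead))
        rows.append(row)
    return pd.DataFrame(rows)
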