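"""Phase-space analyses comparing system variants.

Basin-of-attraction maps over subnetwork initial-condition grids, oscillation
classification from dense trajectories, two-parameter Hopf-boundary scans of
the repressilator family, and memory-amplitude maps M(x^s, 0) with their
zero-level sets.  All analyses are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import find_peaks

from .memory_core import MemoryCalculator
from .network_model import NetworkModel, SubnetworkPartition, build_model
from .projection_integrators import (integrate_full, integrate_qss,
                                     integrate_zms)
from .qss_reduction import FixedPoint, QSSMap, find_fixed_points
from .trajectory import Trajectory

__all__ = [
    "BasinMap",
    "OscillationClassification",
    "BifurcationScan",
    "basin_map",
    "classify_oscillation",
    "hopf_scan",
    "memory_amplitude_map",
    "refine_boundary",
]


# --------------------------------------------------------------------------
# Basins of attraction
# --------------------------------------------------------------------------

@dataclass
class BasinMap:
    """Attractor labels on a subnetwork initial-condition lattice.

    ``labels[variant]`` holds, per grid node (C-order over the axes), the
    index into ``attractors`` of the stable fixed point the trajectory
    reached, or -1 if unresolved within t_max.
    """

    axes: list[np.ndarray]
    attractors: list[np.ndarray]      # subnetwork coordinates of stable FPs
    labels: dict[str, np.ndarray]
    t_max: float
    tol: float

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return tuple(len(a) for a in self.axes)

    def nodes(self) -> np.ndarray:
        mesh = np.meshgrid(*self.axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    def agreement(self, variant: str, reference: str = "full") -> float:
        """Fraction of resolved nodes whose label matches the reference."""
        a, b = self.labels[variant], self.labels[reference]
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            return np.nan
        return float(np.mean(a[ok] == b[ok]))

    def to_frame(self) -> pd.DataFrame:
        nodes = self.nodes()
        df = pd.DataFrame(nodes, columns=[f"x{i+1}" for i in range(nodes.shape[1])])
        for v, lab in self.labels.items():
            df[f"label_{v}"] = lab
        return df


def _variant_integrator(model, partition, variant):
    if variant == "full":
        def run(xs0, t_end):
            return integrate_full(model, xs0, t_end, partition=partition,
                                  bulk_at_qss=True, rtol=1e-7, atol=1e-9)
    elif variant == "qss":
        def run(xs0, t_end):
            return integrate_qss(model, partition, xs0, t_end,
                                 rtol=1e-7, atol=1e-9)
    elif variant == "zms":
        calc = MemoryCalculator(model, partition)

        def run(xs0, t_end):
            return integrate_zms(model, partition, xs0, t_end, calc=calc,
                                 rtol=1e-7, atol=1e-9)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return run


def _variant_state_system(model, partition, variant):
    """(init, rhs, project) triple exposing each variant's internal state, so
    basin runs can be continued in chunks without resetting bulk/memory."""
    sub = np.array(partition.sub, int)
    bulk = np.array(partition.bulk, int)
    ns = len(sub)
    if variant == "full":
        qss = QSSMap(model, partition)

        def init(xs0):
            full = np.empty(model.n_species)
            full[sub] = xs0
            if len(bulk):
                full[bulk] = qss.solve(xs0, guess=np.zeros(len(bulk)))
            return full

        rhs = lambda t, x: model.rates(x)
        project = lambda x: x[sub]
    elif variant == "qss":
        qss = QSSMap(model, partition)
        warm = {"xb": None}

        def rhs(t, x):
            v = qss.drift(x, guess=warm["xb"])
            warm["xb"] = qss._cache_xb
            return v

        init = lambda xs0: np.asarray(xs0, float)
        project = lambda x: x
    elif variant == "zms":
        calc = MemoryCalculator(model, partition)
        nb = len(bulk)
        warm = {"xb": None}

        def rhs(t, z):
            x_s, m = z[:ns], z[ns:]
            ing = calc.ingredients(x_s, guess=warm["xb"])
            warm["xb"] = ing.x_b
            return np.concatenate([ing.drift + ing.f0.T @ m,
                                   ing.c + ing.l.T @ m])

        init = lambda xs0: np.concatenate([np.asarray(xs0, float), np.zeros(nb)])
        project = lambda z: z[:ns]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return init, rhs, project


def basin_map(model: NetworkModel, partition, grid_axes,
              variants: Sequence[str] = ("full", "qss", "zms"),
              attractors: list[np.ndarray] | None = None,
              search_box=None, n_starts: int = 256, t_max: float = 500.0,
              tol: float = 1e-3, chunk: float = 60.0) -> BasinMap:
    """Label each grid node by the attractor its trajectory reaches.

    ``grid_axes`` is one 1-D coordinate array per subnetwork species.  The
    attractor catalogue defaults to the stable fixed points of the full
    system (projected to subnetwork coordinates) found in ``search_box``.
    Full-variant runs initialize the bulk at QSS.  Nodes not within ``tol``
    of an attractor by ``t_max`` are flagged -1, never silently labeled.
    """
    partition = partition or model.partition
    axes = [np.asarray(a, float) for a in grid_axes]
    if attractors is None:
        if search_box is None:
            hi = max(10.0, 2 * max(a.max() for a in axes))
            search_box = [(0.0, hi)] * model.n_species
        fps = find_fixed_points(model, search_box, system="full",
                                partition=partition, n_starts=n_starts)
        attractors = [fp.location[list(partition.sub)] for fp in fps
                      if fp.stability == "stable"]
    if not attractors:
        raise ValueError("no stable attractors found for basin map")

    mesh = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([m.ravel() for m in mesh], axis=-1)
    att = np.asarray(attractors, float)
    sub = list(partition.sub)
    labels: dict[str, np.ndarray] = {}
    from scipy.integrate import solve_ivp

    for variant in variants:
        init, rhs, project = _variant_state_system(model, partition, variant)
        lab = np.full(len(nodes), -1, int)
        for i, xs0 in enumerate(nodes):
            state = init(xs0)
            t_done = 0.0
            while t_done < t_max:
                t_step = min(chunk, t_max - t_done)
                sol = solve_ivp(rhs, (0.0, t_step), state, method="LSODA",
                                rtol=1e-7, atol=1e-9)
                if not sol.success:
                    break
                state = sol.y[:, -1]
                t_done += t_step
                x_end = project(state)
                d = np.max(np.abs(att - x_end), axis=1)
                j = int(np.argmin(d))
                if d[j] < tol:
                    lab[i] = j
                    break
        labels[variant] = lab
    return BasinMap(axes, [a for a in att], labels, t_max, tol)


def refine_boundary(label_fn: Callable[[np.ndarray], int], p_lo: np.ndarray,
                    p_hi: np.ndarray, n_steps: int = 20) -> np.ndarray:
    """Bisect between two points with different labels to locate the
    separatrix crossing on the segment joining them."""
    p_lo = np.asarray(p_lo, float)
    p_hi = np.asarray(p_hi, float)
    lab_lo = label_fn(p_lo)
    if label_fn(p_hi) == lab_lo:
        raise ValueError("endpoints have identical labels; nothing to bisect")
    for _ in range(n_steps):
        mid = 0.5 * (p_lo + p_hi)
        if label_fn(mid) == lab_lo:
            p_lo = mid
        else:
            p_hi = mid
    return 0.5 * (p_lo + p_hi)


# --------------------------------------------------------------------------
# Oscillation classification
# --------------------------------------------------------------------------

@dataclass
class OscillationClassification:
    verdict: str            # converged | damped-oscillatory | sustained-oscillatory | inconclusive
    period: float | None = None
    decay_ratio: float | None = None
    n_peaks: int = 0


def classify_oscillation(traj: Trajectory, observable: int = 0,
                         transient_frac: float = 0.3,
                         sustained_tol: float = 0.01,
                         min_periods: int = 5,
                         n_samples: int = 6000,
                         amp_floor: float = 1e-6) -> OscillationClassification:
    """Classify a trajectory as converged, damped- or sustained-oscillatory.

    Peak detection on the dense output of one observable after discarding the
    first ``transient_frac`` of the window.  *Sustained* requires the
    oscillation envelope (max-min amplitude) of the last half-window --
    containing >= ``min_periods`` periods -- to match the preceding
    half-window within ``1 +/- sustained_tol`` (robust to anharmonic or
    period-doubled cycles); a decaying envelope gives *damped-oscillatory*;
    fewer than two significant extrema give *converged*.  Trajectories too
    short to decide are flagged inconclusive.
    """
    t0 = transient_frac * traj.t_end
    ts = np.linspace(t0, traj.t_end, n_samples)
    z = traj(ts)[:, observable]
    scale = max(np.max(np.abs(z)), 1e-12)
    floor = amp_floor * max(scale, 1.0)
    peaks, _ = find_peaks(z, prominence=floor)
    if len(peaks) < 2:
        return OscillationClassification("converged", n_peaks=len(peaks))
    period = float(np.mean(np.diff(ts[peaks[-10:]])))
    # envelope comparison between the two halves of the post-transient window
    half = n_samples // 2
    A1 = float(np.max(z[:half]) - np.min(z[:half]))
    A2 = float(np.max(z[half:]) - np.min(z[half:]))
    n_peaks_late = int(np.sum(peaks >= half))
    if A1 <= floor or A2 <= floor or n_peaks_late < 1:
        return OscillationClassification("converged", period, None, len(peaks))
    ratio = A2 / A1
    if ratio < 1.0 - sustained_tol:
        return OscillationClassification("damped-oscillatory", period, ratio,
                                         len(peaks))
    if abs(ratio - 1.0) <= sustained_tol and n_peaks_late >= min_periods:
        return OscillationClassification("sustained-oscillatory", period,
                                         ratio, len(peaks))
    return OscillationClassification("inconclusive", period, ratio, len(peaks))


# --------------------------------------------------------------------------
# Hopf scan of the repressilator family
# --------------------------------------------------------------------------

@dataclass
class BifurcationScan:
    """Sustained-oscillation classification over an (a, n) parameter grid."""

    a_values: np.ndarray
    n_values: np.ndarray
    sustained: dict[str, np.ndarray]   # bool arrays, shape (len(n), len(a))
    verdicts: dict[str, np.ndarray]
    eigen_sustained: np.ndarray | None = None  # eigenvalue criterion (full FP)
    eigen_marginal: np.ndarray | None = None

    def boundary_indices(self, variant: str) -> np.ndarray:
        """Per n-row, the first a-index classified sustained (-1 if none)."""
        sus = self.sustained[variant]
        out = np.full(sus.shape[0], -1, int)
        for i, row in enumerate(sus):
            idx = np.flatnonzero(row)
            if len(idx):
                out[i] = idx[0]
        return out


def repressilator_symmetric_point(a: float, n: float) -> float:
    """Root of x (1 + x^n) = a, the symmetric fixed point coordinate."""
    f = lambda x: x * (1 + x ** n) - a
    return brentq(f, 0.0, max(2.0, a), xtol=1e-14)


def hopf_scan(a_values, n_values, variants=("full", "qss", "zms"),
              t_end: float = 160.0, perturbation=(1.3, 0.7),
              marginal_rate: float | None = None,
              sustained_tol: float = 0.01,
              model_builder=None) -> BifurcationScan:
    """Classify (a, n) grid points of the repressilator family per variant.

    Each point is integrated from a fixed off-attractor initial condition
    (the symmetric fixed point scaled componentwise by ``perturbation``; the
    full system's bulk starts at QSS) and classified by
    :func:`classify_oscillation`.  For the full system the eigenvalue-based
    criterion at the symmetric fixed point (max Re lambda > 0) is also
    recorded.  Points with |Re lambda| < ``marginal_rate`` are flagged
    marginal: finite-horizon classification cannot resolve them.  The default
    marginal_rate demands two e-foldings of the leading mode over half the
    post-transient window (2 / (0.35 t_end)).
    """
    if marginal_rate is None:
        marginal_rate = 2.0 / (0.35 * t_end)
    a_values = np.asarray(a_values, float)
    n_values = np.asarray(n_values, float)
    builder = model_builder or (lambda a, n: build_model("repressilator", a=a, n=n))
    shape = (len(n_values), len(a_values))
    sustained = {v: np.zeros(shape, bool) for v in variants}
    verdicts = {v: np.empty(shape, object) for v in variants}
    eig_sus = np.zeros(shape, bool)
    eig_marg = np.zeros(shape, bool)

    for i, n in enumerate(n_values):
        for j, a in enumerate(a_values):
            model = builder(a, n)
            partition = model.partition
            xstar = repressilator_symmetric_point(a, n)
            xs0 = xstar * np.asarray(perturbation, float)[: len(partition.sub)]
            # eigenvalue criterion at the symmetric full fixed point
            full_star = np.full(model.n_species, xstar)
            eig = np.linalg.eigvals(model.jacobian(full_star))
            re_max = float(np.max(eig.real))
            eig_sus[i, j] = re_max > 0
            eig_marg[i, j] = abs(re_max) < marginal_rate
            for v in variants:
                run = _variant_integrator(model, partition, v)
                traj = run(xs0, t_end)
                cl = classify_oscillation(traj, observable=0,
                                          sustained_tol=sustained_tol)
                verdicts[v][i, j] = cl.verdict
                sustained[v][i, j] = cl.verdict == "sustained-oscillatory"
    return BifurcationScan(a_values, n_values, sustained, verdicts,
                           eig_sus, eig_marg)


# --------------------------------------------------------------------------
# Memory amplitude maps
# --------------------------------------------------------------------------

def memory_amplitude_map(model: NetworkModel, partition, grid_axes,
                         calc: MemoryCalculator | None = None):
    """Evaluate the memory amplitude M(x^s, 0) = c(x^s) . f0(x^s) on a grid.

    Returns (field, contours): ``field`` has shape grid_shape + (n_sub,);
    ``contours[s]`` is a list of 2-point segments (linear interpolation on
    grid edges) approximating the zero-level set of species s's amplitude
    (only for 2-D grids; empty otherwise).
    """
    partition = partition or model.partition
    calc = calc or MemoryCalculator(model, partition)
    axes = [np.asarray(a, float) for a in grid_axes]
    mesh = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([m.ravel() for m in mesh], axis=-1)
    f0, _, c, _, _ = calc.ingredients_batch(nodes)
    amp = np.einsum("mb,mbs->ms", c, f0)
    field = amp.reshape(tuple(len(a) for a in axes) + (calc.qss.n_sub,))
    contours = {}
    if len(axes) == 2:
        for s in range(calc.qss.n_sub):
            contours[s] = _zero_segments(axes[0], axes[1], field[:, :, s])
    return field, contours


def _zero_segments(xa, ya, F):
    """Marching-squares zero-level segments of a 2-D scalar field."""
    segs = []
    for i in range(F.shape[0] - 1):
        for j in range(F.shape[1] - 1):
            corners = [
                (xa[i], ya[j], F[i, j]), (xa[i + 1], ya[j], F[i + 1, j]),
                (xa[i + 1], ya[j + 1], F[i + 1, j + 1]),
                (xa[i], ya[j + 1], F[i, j + 1]),
            ]
            pts = []
            for k in range(4):
                x0, y0, f0v = corners[k]
                x1, y1, f1v = corners[(k + 1) % 4]
                if f0v == 0.0:
                    pts.append((x0, y0))
                elif (f0v < 0) != (f1v < 0):
                    t = f0v / (f0v - f1v)
                    pts.append((x0 + t * (x1 - x0), y0 + t * (y1 - y0)))
            if len(pts) >= 2:
                segs.append((pts[0], pts[1]))
    return segs


def amplitude_along(calc: MemoryCalculator, traj: Trajectory,
                    n_samples: int = 800) -> np.ndarray:
    """Memory amplitude evaluated along a subnetwork trajectory; shape
    (n_samples, n_sub).  Useful for counting zero-contour crossings."""
    ts = np.linspace(0.0, traj.t_end, n_samples)
    XS = traj(ts)[:, : calc.qss.n_sub]
    f0, _, c, _, _ = calc.ingredients_batch(XS)
    return np.einsum("mb,mbs->ms", c, f0)
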