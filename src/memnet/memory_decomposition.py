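"""Channel decomposition of the memory, ranking, and ablation.

The memory factorizes over network edges: the prefactor c contains
dR_b''/dx_s' (an *outgoing* channel: subnetwork species s' acting on bulk
species b''), and f0 contains dR_s/dx_b (an *incoming* channel: bulk species
b acting on subnetwork species s).  Expanding both sums decomposes the
memory exactly into quadruple channels (s', b'', b, s) whose contributions
add up to the total; the propagator connecting b'' to b is shared.  Channels
whose defining derivative is identically zero (absent network edges) are
dropped.

For the self-consistent variant, the decomposition carries one auxiliary
m-vector per outgoing channel, so ablated systems (removed channels treated
as instantaneously at QSS) integrate exactly like the full ZMs reduction
restricted to the kept channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import sympy as sp
from scipy.integrate import solve_ivp

from .memory_core import MemoryCalculator
from .network_model import NetworkModel, SubnetworkPartition
from .qss_reduction import QSSMap
from .trajectory import Trajectory
from .projection_integrators import _sub_names

__all__ = [
    "Channel",
    "ChannelSet",
    "ChannelRanking",
    "decompose_channels",
    "rank_channels",
    "ablate_channels",
]


@dataclass(frozen=True)
class Channel:
    """One memory channel: source s' -> (outgoing bulk b'' ... incoming bulk
    b) -> target s.  Indices refer to the species order of the model."""

    source: int
    out_bulk: int
    in_bulk: int
    target: int

    def label(self, species: Sequence[str]) -> str:
        return (f"{species[self.source]}->{species[self.out_bulk]}"
                f"~{species[self.in_bulk]}->{species[self.target]}")


class ChannelSet:
    """The exact additive decomposition of the memory into channels."""

    def __init__(self, model: NetworkModel,
                 partition: SubnetworkPartition | None = None,
                 calc: MemoryCalculator | None = None):
        self.model = model
        self.calc = calc or MemoryCalculator(model, partition)
        self.partition = self.calc.partition
        qss = self.calc.qss
        self._sub = qss._sub
        self._bulk = qss._bulk

        # symbolic sparsity: keep only edges with a not-identically-zero derivative
        exprs = model._exprs
        syms = [model._sym[s] for s in model.species]
        self.out_edges = [
            (sp_i, bb) for sp_i in self._sub for bb in self._bulk
            if sp.simplify(sp.diff(exprs[bb], syms[sp_i])) != 0
        ]
        self.in_edges = [
            (b, s) for b in self._bulk for s in self._sub
            if sp.simplify(sp.diff(exprs[s], syms[b])) != 0
        ]
        self.channels = [
            Channel(sp_i, bb, b, s)
            for (sp_i, bb) in self.out_edges for (b, s) in self.in_edges
        ]

    def __len__(self) -> int:
        return len(self.channels)

    def labels(self) -> list[str]:
        return [ch.label(self.model.species) for ch in self.channels]

    # ------------------------------------------------------------- evaluation
    def _c_channel(self, ing, sp_i: int, bb: int) -> np.ndarray:
        """Outgoing-channel share of the prefactor:
        c^(s',b'')_{b'} = (J^-1)_{b' b''} (dR_b''/dx_s') R_s'."""
        qss = self.calc.qss
        kb = list(self._bulk).index(bb)
        ks = list(self._sub).index(sp_i)
        # column of J^-1 times the single derivative and drift factor
        e = np.zeros(qss.n_bulk)
        e[kb] = 1.0
        col = np.linalg.solve(ing.J, e)
        x_full = np.empty(self.model.n_species)
        x_full[self._sub] = ing.x_s
        x_full[self._bulk] = ing.x_b
        dRb_ds = self.model.jacobian(x_full)[bb, sp_i]
        return col * dRb_ds * ing.drift[ks]

    def evaluate(self, x_s, tau) -> np.ndarray:
        """Per-channel contributions to the memory at (x^s, tau).

        Returns shape (n_channels,), each entry the channel's contribution to
        M on its own target species; contributions summed per target equal
        the total memory function.
        """
        ev = self.calc.memory(x_s, float(tau))
        ing = self.calc.ingredients(ev.x_s)
        f0_y, _, _, _, _ = self.calc.ingredients_batch(ev.transported)
        E = ev.E[0]
        f0y = f0_y[0]
        out = np.empty(len(self.channels))
        c_cache = {}
        bulk_pos = {b: k for k, b in enumerate(self._bulk)}
        sub_pos = {s: k for k, s in enumerate(self._sub)}
        for i, ch in enumerate(self.channels):
            key = (ch.source, ch.out_bulk)
            if key not in c_cache:
                c_cache[key] = self._c_channel(ing, *key)
            c_ch = c_cache[key]
            kb, ks = bulk_pos[ch.in_bulk], sub_pos[ch.target]
            out[i] = (c_ch @ E[:, kb]) * f0y[kb, ks]
        return out

    def total(self, x_s, tau) -> np.ndarray:
        """Total memory function (for additivity checks)."""
        return self.calc.memory(x_s, float(tau)).M[0]


def decompose_channels(model, partition=None) -> ChannelSet:
    return ChannelSet(model, partition)


# --------------------------------------------------------------------------
# Channel-resolved self-consistent integration and ablation
# --------------------------------------------------------------------------

def integrate_zms_channels(channelset: ChannelSet, xs0, t_end,
                           keep: Sequence[Channel] | None = None,
                           t_eval=None, rtol=1e-8, atol=1e-10,
                           method="LSODA") -> Trajectory:
    """Self-consistent integration with one auxiliary m-vector per outgoing
    channel, retaining only the ``keep`` channels in the memory term
    (``keep=None`` keeps all; an empty ``keep`` reproduces the QSS system)."""
    cs = channelset
    calc = cs.calc
    qss = calc.qss
    ns, nb = qss.n_sub, qss.n_bulk
    model = cs.model
    xs0 = np.atleast_1d(np.asarray(xs0, float))
    if keep is None:
        keep = list(cs.channels)
    unknown = [ch for ch in keep if ch not in cs.channels]
    if unknown:
        raise ValueError(f"unknown channel(s): {unknown}")
    keep = list(keep)
    outs = cs.out_edges
    n_out = len(outs)
    bulk_pos = {b: k for k, b in enumerate(cs._bulk)}
    sub_pos = {s: k for k, s in enumerate(cs._sub)}
    # kept (outgoing index o, in_bulk position kb, target position ks)
    kept_triples = [
        (outs.index((ch.source, ch.out_bulk)), bulk_pos[ch.in_bulk],
         sub_pos[ch.target])
        for ch in keep
    ]
    out_sub_pos = np.array([sub_pos[sp_i] for sp_i, _ in outs], int)
    out_bulk_idx = np.array([bb for _, bb in outs], int)
    out_src_idx = np.array([sp_i for sp_i, _ in outs], int)
    warm = {"xb": None}

    def rhs(t, z):
        x_s = z[:ns]
        m = z[ns:].reshape(n_out, nb)
        ing = calc.ingredients(x_s, guess=warm["xb"])
        warm["xb"] = ing.x_b
        x_full = np.empty(model.n_species)
        x_full[cs._sub] = x_s
        x_full[cs._bulk] = ing.x_b
        A = model.jacobian(x_full)
        mem = np.zeros(ns)
        for (o, kb, ks) in kept_triples:
            mem[ks] += m[o, kb] * ing.f0[kb, ks]
        dxs = ing.drift + mem
        # per-outgoing-channel prefactor c^(o) and auxiliary ODEs
        dm = np.empty_like(m)
        Jinv_cols = np.linalg.solve(
            ing.J, np.eye(nb)[:, [bulk_pos[bb] for bb in out_bulk_idx]])
        for o in range(n_out):
            c_o = Jinv_cols[:, o] * A[out_bulk_idx[o], out_src_idx[o]] \
                * ing.drift[out_sub_pos[o]]
            dm[o] = c_o + ing.l.T @ m[o]
        return np.concatenate([dxs, dm.ravel()])

    z0 = np.concatenate([xs0, np.zeros(n_out * nb)])
    sol = solve_ivp(rhs, (0.0, float(t_end)), z0, method=method, rtol=rtol,
                    atol=atol, dense_output=True, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"channel ZMs integration failed: {sol.message}")
    times = np.asarray(sol.t)
    Z = np.asarray(sol.y).T
    dense_aug = sol.sol

    def dense(t):
        return np.asarray(dense_aug(t))[:ns]

    return Trajectory(times, Z[:, :ns], "zms", dense=dense,
                      names=_sub_names(model, cs.partition),
                      aux={"m_channels": Z[:, ns:].reshape(len(times), n_out, nb),
                           "dense_augmented": dense_aug, "channelset": cs,
                           "keep": keep})


def ablate_channels(model, partition, keep: Sequence[Channel],
                    channelset: ChannelSet | None = None):
    """Return an integrator with only ``keep`` channels active in the memory
    (removed channels' pathways are treated as instantaneously at QSS).

    The returned callable has signature ``integrate(xs0, t_end, **options)``.
    ``keep=[]`` reproduces the QSS system; keeping all channels reproduces the
    full self-consistent reduction.
    """
    cs = channelset or ChannelSet(model, partition)

    def integrate(xs0, t_end, **options) -> Trajectory:
        return integrate_zms_channels(cs, xs0, t_end, keep=keep, **options)

    return integrate


# --------------------------------------------------------------------------
# Ranking
# --------------------------------------------------------------------------

@dataclass
class ChannelRanking:
    """Normalized per-channel importance along one trajectory."""

    channels: list[Channel]
    scores: np.ndarray        # normalized, sum to 1 (unless degenerate)
    raw_scores: np.ndarray
    metric: str
    degenerate: bool = False

    def to_frame(self, species=None) -> pd.DataFrame:
        rows = []
        for ch, s, r in zip(self.channels, self.scores, self.raw_scores):
            rows.append({
                "channel": ch.label(species) if species else str(ch),
                "source": ch.source, "out_bulk": ch.out_bulk,
                "in_bulk": ch.in_bulk, "target": ch.target,
                "score": s, "raw_score": r,
            })
        return pd.DataFrame(rows).sort_values("score", ascending=False,
                                              ignore_index=True)

    def by_pair(self) -> dict[tuple[int, int], float]:
        """Aggregated sender -> receiver view (sums quadruple scores)."""
        agg: dict[tuple[int, int], float] = {}
        for ch, s in zip(self.channels, self.scores):
            key = (ch.source, ch.target)
            agg[key] = agg.get(key, 0.0) + float(s)
        return agg

    def by_out_bulk(self) -> dict[int, float]:
        """Aggregated by the bulk species receiving the outgoing edge."""
        agg: dict[int, float] = {}
        for ch, s in zip(self.channels, self.scores):
            agg[ch.out_bulk] = agg.get(ch.out_bulk, 0.0) + float(s)
        return agg

    def top(self, k: int) -> list[Channel]:
        order = np.argsort(self.scores)[::-1]
        return [self.channels[i] for i in order[:k]]

    def to_dot(self, species) -> str:
        lines = ["digraph memory_channels {"]
        for (src, tgt), s in sorted(self.by_pair().items(),
                                    key=lambda kv: -kv[1]):
            if s > 0:
                lines.append(
                    f'  "{species[src]}" -> "{species[tgt]}" '
                    f'[label="{s:.3f}", penwidth={max(0.5, 6 * s):.2f}];')
        lines.append("}")
        return "\n".join(lines)


def rank_channels(channelset: ChannelSet, trajectory: Trajectory,
                  metric: str = "integrated_abs",
                  n_samples: int = 400) -> ChannelRanking:
    """Score channels by their contribution to dx^s/dt along a trajectory.

    The trajectory must come from the channel-resolved self-consistent
    integrator on the same model/partition (a plain ZMs trajectory is
    re-integrated channel-resolved from the same initial condition).
    Metrics: ``integrated_abs`` (default) integrates the absolute channel
    contribution over time; ``integrated_signed`` keeps the sign;
    ``max_abs`` takes the peak contribution.  Scores are normalized to sum 1;
    an all-zero ranking (e.g. a trajectory resting at a fixed point) is
    flagged degenerate.
    """
    cs = channelset
    if trajectory.variant != "zms":
        raise ValueError("ranking requires a self-consistent (zms) trajectory")
    if "m_channels" not in trajectory.aux:
        traj_cs = trajectory.aux.get("channelset")
        if traj_cs is not None and traj_cs is not cs:
            raise ValueError("trajectory was produced with a different channel set")
        trajectory = integrate_zms_channels(cs, trajectory.states[0],
                                            trajectory.t_end)
    elif trajectory.aux.get("channelset") is not cs:
        raise ValueError("trajectory was produced with a different channel set")

    calc = cs.calc
    ns, nb = calc.qss.n_sub, calc.qss.n_bulk
    n_out = len(cs.out_edges)
    ts = np.linspace(0.0, trajectory.t_end, n_samples)
    Z = np.asarray(trajectory.aux["dense_augmented"](ts))
    XS = Z[:ns].T
    Mch = Z[ns:].T.reshape(len(ts), n_out, nb)
    f0, _, _, _, _ = calc.ingredients_batch(XS)
    bulk_pos = {b: k for k, b in enumerate(cs._bulk)}
    sub_pos = {s: k for k, s in enumerate(cs._sub)}
    contrib = np.empty((len(ts), len(cs.channels)))
    for i, ch in enumerate(cs.channels):
        o = cs.out_edges.index((ch.source, ch.out_bulk))
        kb, ks = bulk_pos[ch.in_bulk], sub_pos[ch.target]
        contrib[:, i] = Mch[:, o, kb] * f0[:, kb, ks]

    if metric == "integrated_abs":
        raw = np.trapezoid(np.abs(contrib), ts, axis=0)
    elif metric == "integrated_signed":
        raw = np.trapezoid(contrib, ts, axis=0)
    elif metric == "max_abs":
        raw = np.max(np.abs(contrib), axis=0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    total = np.sum(np.abs(raw))
    if total < 1e-300:
        return ChannelRanking(list(cs.channels), np.zeros(len(cs.channels)),
                              raw, metric, degenerate=True)
    return ChannelRanking(list(cs.channels), np.abs(raw) / total, raw, metric)
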