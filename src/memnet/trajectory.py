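"""Time-course container shared by all integrators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd


@dataclass
class Trajectory:
    """A solved time course with dense interpolation.

    ``states`` has shape (len(times), dim); ``dense`` maps a time (scalar or
    array) to the state; at the stored grid times it reproduces ``states``
    exactly.  ``variant`` tags which system produced it (full | qss | zmn |
    zms).  ``aux`` carries integrator-specific extras (e.g. the auxiliary
    memory vector of the self-consistent reduction).
    """

    times: np.ndarray
    states: np.ndarray
    variant: str
    dense: Optional[Callable[[float], np.ndarray]] = None
    names: Optional[tuple[str, ...]] = None
    aux: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.states = np.asarray(self.states, float)
        if self.times.ndim != 1 or self.times[0] != 0.0:
            raise ValueError("trajectory times must be 1-D and start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("times/states length mismatch")

    @property
    def dim(self) -> int:
        return self.states.shape[1]

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def __call__(self, t):
        """Dense-evaluate the state at time(s) t."""
        if self.dense is None:
            raise ValueError("trajectory has no dense evaluator")
        t = np.asarray(t, float)
        out = np.asarray(self.dense(t), float)
        if t.ndim == 0:
            return out.reshape(-1)
        # solve_ivp dense output returns (dim, nt); normalize to (nt, dim)
        if out.shape[0] == self.dim and out.shape[-1] == t.shape[0]:
            out = out.T
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = self.names or tuple(f"y{i}" for i in range(self.dim))
        df = pd.DataFrame(self.states, columns=list(cols))
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def metadata(self) -> dict:
        meta = {"variant": self.variant, "t_end": self.t_end,
                "n_points": int(len(self.times)),
                "names": list(self.names) if self.names else None}
        meta.update({k: v for k, v in self.aux.items()
                     if isinstance(v, (str, int, float))})
        return meta

    def to_json(self, path) -> None:
        """Write run metadata (variant, grid size, options) as JSON."""
        import json
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


def from_solve_ivp(sol, variant: str, names=None, aux=None) -> Trajectory:
    """Wrap a scipy ``solve_ivp`` result (dense_output=True) as a Trajectory."""
    times = np.asarray(sol.t, float)
    states = np.asarray(sol.y, float).T
    return Trajectory(times, states, variant, dense=sol.sol, names=names,
                      aux=aux or {})
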