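"""Dynamical network models: definition, parsing, evaluation, differentiation.

A :class:`NetworkModel` is a system of autonomous ODEs ``dx/dt = R(x)`` with
one closed-form rate expression per species.  Expressions may use arithmetic,
powers (``^`` or ``**``), ``exp`` and ``log``; every free symbol must be a
declared species or parameter.  Models can be built from a YAML/JSON config
or from one of the built-in fixture networks (cross-repressive switches, the
repressilator, a four-factor neural-tube-style circuit, and a bulk-linear
demonstration model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import sympy as sp
import yaml
from sympy.core.function import AppliedUndef

__all__ = [
    "NetworkModel",
    "SubnetworkPartition",
    "ModelValidationError",
    "EvaluationError",
    "build_model",
    "FIXTURES",
]


class ModelValidationError(ValueError):
    """Raised when a model definition is inconsistent or unparsable."""


class EvaluationError(RuntimeError):
    """Raised when rate or derivative evaluation produces non-finite values."""


_ALLOWED_FUNCS = {"exp": sp.exp, "log": sp.log, "sqrt": sp.sqrt}


def _parse_expression(text: str, symbols: Mapping[str, sp.Symbol]) -> sp.Expr:
    local = dict(symbols)
    local.update(_ALLOWED_FUNCS)
    try:
        expr = sp.sympify(str(text).replace("^", "**"), locals=local)
    except (sp.SympifyError, SyntaxError, TypeError) as exc:
        raise ModelValidationError(f"cannot parse rate expression {text!r}: {exc}") from exc
    undef = expr.atoms(AppliedUndef)
    if undef:
        names = ", ".join(sorted(str(f.func) for f in undef))
        raise ModelValidationError(f"unknown function(s) {names} in expression {text!r}")
    return expr


@dataclass(frozen=True)
class SubnetworkPartition:
    """Disjoint split of species indices into subnetwork and bulk.

    The subnetwork species are retained explicitly by the reduced dynamics;
    the bulk species are eliminated and represented through memory terms.
    """

    sub: tuple[int, ...]
    bulk: tuple[int, ...]

    def __post_init__(self):
        sub, bulk = tuple(self.sub), tuple(self.bulk)
        object.__setattr__(self, "sub", sub)
        object.__setattr__(self, "bulk", bulk)
        if not sub:
            raise ModelValidationError("subnetwork must contain at least one species")
        if set(sub) & set(bulk):
            raise ModelValidationError("subnetwork and bulk indices overlap")
        if len(set(sub)) != len(sub) or len(set(bulk)) != len(bulk):
            raise ModelValidationError("duplicate indices in partition")

    @property
    def n_sub(self) -> int:
        return len(self.sub)

    @property
    def n_bulk(self) -> int:
        return len(self.bulk)

    def validate_for(self, model: "NetworkModel") -> None:
        n = len(model.species)
        if set(self.sub) | set(self.bulk) != set(range(n)):
            raise ModelValidationError(
                "partition does not cover all species indices of the model"
            )

    @classmethod
    def from_names(cls, model: "NetworkModel", sub_names: Sequence[str]) -> "SubnetworkPartition":
        idx = {name: i for i, name in enumerate(model.species)}
        for name in sub_names:
            if name not in idx:
                raise ModelValidationError(f"unknown species {name!r} in partition")
        sub = tuple(idx[name] for name in sub_names)
        bulk = tuple(i for i in range(len(model.species)) if i not in sub)
        part = cls(sub, bulk)
        part.validate_for(model)
        return part

    def assemble(self, x_s: np.ndarray, x_b: np.ndarray) -> np.ndarray:
        """Interleave subnetwork and bulk coordinates into a full state."""
        x_s = np.atleast_1d(np.asarray(x_s, float))
        x_b = np.atleast_1d(np.asarray(x_b, float)) if self.n_bulk else np.empty(0)
        full = np.empty(x_s.shape[:-1] + (self.n_sub + self.n_bulk,))
        full[..., list(self.sub)] = x_s
        if self.n_bulk:
            full[..., list(self.bulk)] = x_b
        return full


class NetworkModel:
    """A deterministic reaction/regulation network ``dx/dt = R(x)``.

    Parameters
    ----------
    species
        Ordered species names (must be valid identifiers).
    rates
        Mapping from species name to its rate expression as a string (or a
        sympy expression) in the species and parameter symbols.
    params
        Mapping from parameter name to numeric value.
    derivative_mode
        ``"symbolic"`` (default) differentiates the parsed expressions with
        sympy; ``"fd"`` uses central finite differences with step
        ``max(1e-6, 1e-6 |x_j|)``.  Symbolic derivatives are cross-checked
        against finite differences in the test-suite.
    partition
        Optional default :class:`SubnetworkPartition` (fixtures set one).
    """

    def __init__(
        self,
        species: Sequence[str],
        rates: Mapping[str, object],
        params: Mapping[str, float] | None = None,
        derivative_mode: str = "symbolic",
        partition: SubnetworkPartition | None = None,
        name: str | None = None,
    ):
        self.species = tuple(str(s) for s in species)
        if len(set(self.species)) != len(self.species):
            raise ModelValidationError("duplicate species names")
        self.params = {str(k): float(v) for k, v in (params or {}).items()}
        if set(self.params) & set(self.species):
            clash = sorted(set(self.params) & set(self.species))
            raise ModelValidationError(f"names used both as species and parameter: {clash}")
        if derivative_mode not in ("symbolic", "fd"):
            raise ModelValidationError(f"unknown derivative_mode {derivative_mode!r}")
        self.derivative_mode = derivative_mode
        self.name = name

        if set(rates) != set(self.species):
            missing = sorted(set(self.species) - set(rates))
            extra = sorted(set(rates) - set(self.species))
            raise ModelValidationError(
                f"rates must match species exactly (missing: {missing}, extra: {extra})"
            )

        self._sym = {s: sp.Symbol(s, real=True) for s in self.species}
        self._par = {p: sp.Symbol(p, real=True) for p in self.params}
        allowed = {**self._sym, **self._par}
        self._raw_exprs: list[sp.Expr] = []
        for s in self.species:
            expr = rates[s]
            if not isinstance(expr, sp.Expr):
                expr = _parse_expression(expr, allowed)
            free = expr.free_symbols - set(allowed.values())
            if free:
                names = ", ".join(sorted(str(f) for f in free))
                raise ModelValidationError(
                    f"undeclared symbol(s) {names} in rate of species {s!r}"
                )
            self._raw_exprs.append(expr)
        self._rate_strings = {s: str(rates[s]) for s in self.species}

        subs = {self._par[p]: sp.Float(v) for p, v in self.params.items()}
        self._exprs = [e.xreplace(subs) for e in self._raw_exprs]
        args = [self._sym[s] for s in self.species]
        self._rate_fn = sp.lambdify(args, self._exprs, modules="numpy")
        jac = sp.Matrix(self._exprs).jacobian(sp.Matrix(args))
        self._jac_exprs = jac
        self._jac_fn = sp.lambdify(args, jac.tolist(), modules="numpy")

        self.partition = partition
        if partition is not None:
            partition.validate_for(self)

    # ------------------------------------------------------------------ eval
    @property
    def n_species(self) -> int:
        return len(self.species)

    def rates(self, x: Sequence[float]) -> np.ndarray:
        """Evaluate R(x) at a single state."""
        x = np.asarray(x, float)
        if x.shape != (self.n_species,):
            raise ValueError(f"state must have shape ({self.n_species},), got {x.shape}")
        with np.errstate(all="ignore"):
            vals = np.array(self._rate_fn(*x), float)
        bad = ~np.isfinite(vals)
        if bad.any():
            names = [self.species[i] for i in np.flatnonzero(bad)]
            raise EvaluationError(f"non-finite rate for species {names} at state {x}")
        return vals

    def rates_batch(self, X: np.ndarray) -> np.ndarray:
        """Evaluate R at many states at once; X has shape (m, n_species)."""
        X = np.asarray(X, float)
        with np.errstate(all="ignore"):
            cols = self._rate_fn(*(X[:, j] for j in range(self.n_species)))
        out = np.empty_like(X)
        for j, col in enumerate(cols):
            out[:, j] = col
        if not np.isfinite(out).all():
            raise EvaluationError("non-finite rate in batch evaluation")
        return out

    def jacobian(self, x: Sequence[float]) -> np.ndarray:
        """Matrix of partial derivatives dR_i/dx_j at a state."""
        x = np.asarray(x, float)
        if self.derivative_mode == "fd":
            return self.jacobian_fd(x)
        with np.errstate(all="ignore"):
            rows = self._jac_fn(*x)
        J = np.asarray(rows, float)
        if not np.isfinite(J).all():
            raise EvaluationError(f"non-finite derivative at state {x}")
        return J

    def jacobian_batch(self, X: np.ndarray) -> np.ndarray:
        """Batch Jacobians, shape (m, n, n)."""
        X = np.asarray(X, float)
        m, n = X.shape
        with np.errstate(all="ignore"):
            rows = self._jac_fn(*(X[:, j] for j in range(n)))
        J = np.empty((m, n, n))
        for i, row in enumerate(rows):
            for j, val in enumerate(row):
                J[:, i, j] = val
        if not np.isfinite(J).all():
            raise EvaluationError("non-finite derivative in batch evaluation")
        return J

    def jacobian_fd(self, x: Sequence[float]) -> np.ndarray:
        """Central finite-difference Jacobian (the universal cross-check)."""
        x = np.asarray(x, float)
        n = self.n_species
        J = np.empty((n, n))
        for j in range(n):
            h = max(1e-6, 1e-6 * abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            J[:, j] = (self.rates(xp) - self.rates(xm)) / (2 * h)
        return J

    # ----------------------------------------------------------------- admin
    def with_params(self, **overrides: float) -> "NetworkModel":
        """Return a copy with some parameter values replaced."""
        unknown = sorted(set(overrides) - set(self.params))
        if unknown:
            raise ModelValidationError(f"unknown parameter(s) {unknown}")
        params = {**self.params, **overrides}
        return NetworkModel(
            self.species,
            {s: e for s, e in zip(self.species, self._raw_exprs)},
            params,
            derivative_mode=self.derivative_mode,
            partition=self.partition,
            name=self.name,
        )

    def to_config(self) -> dict:
        """Serializable dict representation (round-trips through YAML/JSON)."""
        cfg = {
            "species": list(self.species),
            "rates": {s: str(e) for s, e in zip(self.species, self._raw_exprs)},
            "params": dict(self.params),
        }
        if self.partition is not None:
            cfg["partition"] = {
                "sub": [self.species[i] for i in self.partition.sub],
                "bulk": [self.species[i] for i in self.partition.bulk],
            }
        return cfg

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_config(), sort_keys=False)

    def __repr__(self) -> str:  # pragma: no cover
        tag = self.name or "NetworkModel"
        return f"<{tag}: {len(self.species)} species {list(self.species)}>"


# --------------------------------------------------------------------------
# Fixture networks
# --------------------------------------------------------------------------
#
# Hill terms x^n are written as (x^2)^(n/2) == |x|^n: identical on the
# nonnegative orthant where the models live, but smooth and finite for the
# small zero-crossings that memory-corrected reduced trajectories can
# produce at oscillation troughs (important for non-integer n).

def _hill(x: str) -> str:
    return f"(({x})^2)^(n/2)"


def _bistable2(a: float = 6.0, n: float = 3.0) -> NetworkModel:
    """Two-node mutual-repression switch (Hill 'or' logic).

    Defaults a=6, n=3 give stable states near (6, 0.028)/(0.028, 6) and a
    symmetric saddle near (1.46, 1.46).  Default partition: x1 subnetwork,
    x2 bulk.
    """
    model = NetworkModel(
        ["x1", "x2"],
        {"x1": f"a/(1 + {_hill('x2')}) - x1", "x2": f"a/(1 + {_hill('x1')}) - x2"},
        {"a": a, "n": n},
        name="bistable2",
    )
    model.partition = SubnetworkPartition((0,), (1,))
    return model


def _multistable_or(N: int = 3, a: float = 4.0, n: float = 2.0) -> NetworkModel:
    """N mutually repressive species, dx_j/dt = a/(1+sum_{i!=j} x_i^n) - x_j.

    For N=3, a=4, n=2 this is tetrastable: three high-low-low states plus a
    symmetric one.  Default partition: first two species subnetwork, rest bulk.
    """
    N = int(N)
    if N < 2:
        raise ModelValidationError("multistable_or requires N >= 2")
    species = [f"x{j}" for j in range(1, N + 1)]
    rates = {}
    for j, s in enumerate(species):
        others = " + ".join(_hill(o) for k, o in enumerate(species) if k != j)
        rates[s] = f"a/(1 + {others}) - {s}"
    model = NetworkModel(species, rates, {"a": a, "n": n}, name=f"multistable_or{N}")
    n_sub = min(2, N - 1)
    model.partition = SubnetworkPartition(tuple(range(n_sub)), tuple(range(n_sub, N)))
    return model


def _repressilator(a: float = 5.0, n: float = 3.0) -> NetworkModel:
    """Three-gene cyclic repression ring, dx_j/dt = a/(1+x_{j-1}^n) - x_j.

    Cyclic indexing (x0 = x3).  Default partition: {x1, x2} subnetwork,
    {x3} bulk.
    """
    model = NetworkModel(
        ["x1", "x2", "x3"],
        {
            "x1": f"a/(1 + {_hill('x3')}) - x1",
            "x2": f"a/(1 + {_hill('x1')}) - x2",
            "x3": f"a/(1 + {_hill('x2')}) - x3",
        },
        {"a": a, "n": n},
        name="repressilator",
    )
    model.partition = SubnetworkPartition((0, 1), (2,))
    return model


def _neural_tube4(p: float = 0.65, **overrides: float) -> NetworkModel:
    """Illustrative four-factor neural-tube-style circuit.

    Species Nkx (Nkx2.2-like), Olig (Olig2-like), Irx (Irx3-like) and Pax
    (Pax6-like) with the cross-repressive topology of the vertebrate
    neural-tube patterning circuit and a scalar morphogen signal p in [0, 1]
    activating Nkx and Olig.  Repression weights are asymmetric: Nkx
    represses Olig strongly (wNO) while Olig feels its bulk partner Irx only
    weakly (wIO), so Olig responds first when the signal turns on but Nkx
    wins where both are induced.  At intermediate signal (default p=0.65)
    the circuit is tristable: both-low with Irx/Pax high (p2-like), Olig
    high (pMN-like) and Nkx high (p3-like).  The parametrization is
    illustrative, chosen for these qualitative regimes, NOT a published fit;
    analyses on this fixture are qualitative.  Default partition:
    {Nkx, Olig} subnetwork, {Irx, Pax} bulk.
    """
    params = {
        "p": p,
        "aN": 5.0,
        "aO": 5.0,
        "aI": 4.0,
        "aP": 4.0,
        "n": 3.0,
        "wON": 1.0,
        "wPN": 1.0,
        "wNO": 4.0,
        "wIO": 0.3,
        "wNI": 1.0,
        "wOI": 1.0,
        "wNP": 1.0,
        "wOP": 1.0,
    }
    params.update(overrides)
    model = NetworkModel(
        ["Nkx", "Olig", "Irx", "Pax"],
        {
            "Nkx": f"aN*p/(1 + wON*{_hill('Olig')} + wPN*{_hill('Pax')}) - Nkx",
            "Olig": f"aO*p/(1 + wNO*{_hill('Nkx')} + wIO*{_hill('Irx')}) - Olig",
            "Irx": f"aI/(1 + wNI*{_hill('Nkx')} + wOI*{_hill('Olig')}) - Irx",
            "Pax": f"aP/(1 + wNP*{_hill('Nkx')} + wOP*{_hill('Olig')}) - Pax",
        },
        params,
        name="neural_tube4",
    )
    model.partition = SubnetworkPartition((0, 1), (2, 3))
    return model


def _linear_bulk_demo(**overrides: float) -> NetworkModel:
    """One subnetwork species coupled to a two-species bulk that enters all
    rates linearly, with a non-symmetric Hurwitz bulk matrix.

    Because R^s and R^b are at most linear in the bulk species, the
    self-consistent memory reduction is exact on this model; it doubles as
    the end-to-end certification of propagator orientation.
    """
    params = {
        "u0": 0.5, "w12": 0.6, "w13": 0.3,
        "a2": 4.0, "n2": 3.0, "d2": 1.5, "q23": 0.4,
        "a3": 1.0, "q32": 0.3, "d3": 2.0,
    }
    params.update(overrides)
    model = NetworkModel(
        ["x1", "x2", "x3"],
        {
            "x1": "u0 - x1 + w12*x2 - w13*x3",
            "x2": "a2/(1 + (x1^2)^(n2/2)) - d2*x2 + q23*x3",
            "x3": "a3*x1^2/(1 + x1^2) + q32*x2 - d3*x3",
        },
        params,
        name="linear_bulk_demo",
    )
    model.partition = SubnetworkPartition((0,), (1, 2))
    return model


FIXTURES: dict[str, Callable[..., NetworkModel]] = {
    "bistable2": _bistable2,
    "multistable_or": _multistable_or,
    "repressilator": _repressilator,
    "neural_tube4": _neural_tube4,
    "linear_bulk_demo": _linear_bulk_demo,
}


def build_model(spec: str | Mapping, **overrides) -> NetworkModel:
    """Build a :class:`NetworkModel` from a fixture name, config text, or dict.

    ``spec`` may be the name of a built-in fixture (``bistable2``,
    ``multistable_or``, ``repressilator``, ``neural_tube4``,
    ``linear_bulk_demo``), YAML/JSON config text, or a pre-parsed mapping with
    keys ``species``, ``rates``, ``params`` and optionally ``partition``.
    Keyword overrides are fixture parameters (e.g. ``a=6, n=3`` or ``N=3``).
    """
    if isinstance(spec, str) and spec in FIXTURES:
        return FIXTURES[spec](**overrides)
    if isinstance(spec, Mapping):
        cfg = dict(spec)
    else:
        try:
            cfg = yaml.safe_load(spec)
        except yaml.YAMLError as exc:
            raise ModelValidationError(f"cannot parse model config: {exc}") from exc
        if isinstance(cfg, str) or cfg is None:
            raise ModelValidationError(
                f"unknown fixture or invalid config {spec!r}; "
                f"known fixtures: {sorted(FIXTURES)}"
            )
    if overrides:
        cfg = dict(cfg)
        cfg["params"] = {**cfg.get("params", {}), **overrides}
    for key in ("species", "rates"):
        if key not in cfg:
            raise ModelValidationError(f"model config missing required key {key!r}")
    model = NetworkModel(cfg["species"], cfg["rates"], cfg.get("params", {}),
                         derivative_mode=cfg.get("derivative_mode", "symbolic"),
                         name=cfg.get("name"))
    if "partition" in cfg and cfg["partition"]:
        part = cfg["partition"]
        model.partition = SubnetworkPartition.from_names(model, part["sub"])
        declared_bulk = part.get("bulk")
        if declared_bulk is not None:
            expected = [model.species[i] for i in model.partition.bulk]
            if list(declared_bulk) != expected:
                model.partition = SubnetworkPartition(
                    tuple(model.species.index(s) for s in part["sub"]),
                    tuple(model.species.index(s) for s in declared_bulk),
                )
                model.partition.validate_for(model)
    return model
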