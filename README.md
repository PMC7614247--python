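# memnet

Reduce a deterministic dynamical network — e.g. a gene regulatory circuit —
to an arbitrary subnetwork while keeping the dynamics of the eliminated
species, via explicitly computable nonlinear memory functions.

## The problem

Given a network `dx/dt = R(x)` split into a *subnetwork* `x^s` (tracked
explicitly) and a *bulk* `x^b` (to be eliminated), the crudest reduction is
the quasi-steady-state (QSS) approximation: assume the bulk relaxes
instantly to the state `x^b*(x^s)` solving `R^b(x^s, x^b*) = 0`, giving the
memoryless drift `v(x^s) = R^s(x^s, x^b*(x^s))`.  Real bulks are not
instantaneous: they store the recent history of the subnetwork and feed it
back later.  Projection-operator (Zwanzig–Mori) theory makes this correction
exact in the form

```
dx^s/dt = v(x^s(t)) + ∫₀ᵗ dt′ M(x^s(t′), t − t′)
```

but the memory function `M` is in general incomputable.  This package
implements a closed form obtained by linearizing the bulk around its QSS:

```
M_s(x^s, τ)  =  Σ_b′ c_b′(x^s) · f_{b′s}(x^s, τ)
f_{bs}(x^s, τ) =  Σ_b′ E_{bb′}(τ) · f⁰_{b′s}(φ_v(x^s, τ))
```

with ingredients evaluated at `(x^s, x^b*(x^s))`:

- `f⁰_{bs} = ∂R_s/∂x_b` — how bulk deviations perturb the subnetwork drift,
- `J_{b″b′} = ∂R_{b″}/∂x_{b′}` — the bulk Jacobian,
- `l_{bb′} = J_{b′b} + Σ_{s′b″} (J⁻¹)_{b′b″} (∂R_{b″}/∂x_{s′}) (∂R_{s′}/∂x_b)`,
- `c_{b′} = Σ_{s′b″} (J⁻¹)_{b′b″} (∂R_{b″}/∂x_{s′}) R_{s′}` — the memory
  prefactor, proportional to the QSS drift (so memory vanishes at fixed
  points),
- `E(τ)` — the time-ordered exponential of `l` along the QSS flow `φ_v`.

Two reduced systems are provided: **ZMn** integrates the memory integral
above directly; **ZMs** (self-consistent, the default) propagates the memory
along the actual corrected trajectory and is evaluated through one auxiliary
ODE per bulk species (`dm/dt = c + lᵀ m`, memory term `Σ_b m_b f⁰_{bs}`).
ZMs is *exact* whenever the rates are at most linear in the bulk species,
and both variants linearize near fixed points to a convolution kernel that
reproduces the full linearized dynamics exactly.

The memory also decomposes exactly into *channels* — (subnetwork source →
bulk mediator → subnetwork target) paths — which can be ranked along a
trajectory and ablated (set to QSS) to identify which interactions carry the
dynamically relevant history.

## Worked example

The classic two-node mutual-repression switch
`dx₁/dt = a/(1+x₂ⁿ) − x₁`, `dx₂/dt = a/(1+x₁ⁿ) − x₂` with `a=6, n=3`,
placing `x₂` in the bulk:

```python
import numpy as np
import memnet as mn

model = mn.build_model("bistable2", a=6, n=3)
fps = mn.find_fixed_points(model, [(0, 10)] * 2, system="full")
for fp in fps:
    print(np.round(fp.location, 4), fp.stability)
```

prints the two stable states and the saddle between them:

```
[0.0277 5.9999] stable
[1.4597 1.4597] saddle
[5.9999 0.0277] stable
```

Starting just above the saddle, the memoryless QSS reduction reaches the
high state too fast, while the memory-corrected reductions track the full
transient:

```python
part = model.partition           # x1 subnetwork, x2 bulk
full = mn.integrate_full(model, [2.0], 50, partition=part, bulk_at_qss=True)
zms  = mn.integrate_zms(model, part, [2.0], 50)
qss  = mn.integrate_qss(model, part, [2.0], 50)
ts = np.linspace(0, 50, 501)
gap = 5.9999 - 0.0277
print("zms error: %.3f" % (np.max(np.abs(full(ts)[:, 0] - zms(ts)[:, 0])) / gap))
print("qss error: %.3f" % (np.max(np.abs(full(ts)[:, 0] - qss(ts)[:, 0])) / gap))
```

```
zms error: 0.045
qss error: 0.069
```

(sup-norm deviation from the full system's `x₁(t)`, as a fraction of the
distance between the two stable states).

## Built-in networks

| fixture | description |
|---|---|
| `bistable2` | two-node mutual-repression switch (a=6, n=3) |
| `multistable_or` | N mutually repressive species; N=3, a=4, n=2 is tetrastable |
| `repressilator` | three-gene repression ring; damped or sustained oscillations |
| `neural_tube4` | illustrative 4-factor neural-tube-style circuit with a morphogen signal `p` |
| `linear_bulk_demo` | bulk-linear rates: the self-consistent reduction is exact |

Custom models are YAML/JSON configs with `species`, `rates` (closed-form
expressions; `^` or `**` for powers, `exp`/`log` allowed), `params` and an
optional `partition`.

## Command line

```bash
memnet simulate --model bistable2 --variant zms --x0 2.0 --t-end 50 --out traj.csv
memnet fixed-points --model bistable2 --box 0:10 --out fps.csv
memnet basins --model multistable_or --grid 0:4:21 --grid 0:4:21 --out basins.csv
memnet hopf-scan --a-grid 1:10:13 --n-grid 2.6:5:9 --out scan.csv
memnet memory-map --model repressilator --grid 0.3:3:40 --grid 0.3:3:40 --out map.csv
memnet decompose --model neural_tube4 --x0 1.4,0.3 --t-end 40 --out rank.csv
```

Longer demonstrations (tristable fate maps, transient analysis with channel
ranking and ablation) are in `examples/`.

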