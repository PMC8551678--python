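# leafhydraulics

Spatially explicit resistor–capacitor modelling of leaf xylem water
transport.

Water moves through a leaf the way current moves through a leaky cable:
the xylem is a chain of resistors, every point along the blade loses
water to the atmosphere through stomata (a distributed leak), and
water-storage cells — bulliform cells, bundle sheaths, storage
parenchyma — act as local capacitors that buffer the water status when
conditions change. This package implements that circuit analog for
plant biophysicists who want to ask: *how does the water potential vary
from leaf base to tip, how fast does a leaf dehydrate when its supply
is cut or the air dries, and how much of that robustness is bought by
storage capacitance?*

## The model

A leaf is a network of nodes `i = 1..N`. Node potentials `ψᵢ` (MPa)
obey Kirchhoff's laws with three branch types:

- xylem segments between neighbours: `ψᵢ₋₁ − ψᵢ = Rᵢ₋₁,ᵢ · Iᵢ₋₁,ᵢ`
- a stomatal path to the atmosphere at `ψₐ`: `ψᵢ − ψₐ = Rᵢ⁽ᵃ⁾ · Iᵢ⁽ᵃ⁾`
  (closed stomata = infinite `Rᵃ`)
- a storage branch: capacitance `Cᵢ` behind resistance `Rᵢ⁽ᶜ⁾`, whose
  voltage is the cell turgor.

Steady states solve a symmetric linear system `B·ψ = a` (graph
Laplacian plus boundary conductances); transients advance the rate
system `A·(dψ/dt) = b` with explicit first-order stepping (default
`Δt = 0.01 min`). Total transpiration is `E = Σᵢ Iᵢ⁽ᵃ⁾`.

For the *uniform* one-dimensional leaf with whole-leaf parameters
(`R`, `Ra`, `Rc`, `C`), closed forms are provided: the steady profile
`ψ(x) = ψₐ + (ψ₀−ψₐ)·cosh(m(1−x))/cosh(m)` with `m = √(R/Ra)` and a
sealed tip, the base influx `I₀ = (ψ₀−ψₐ)(m/R)·tanh(m)`, the mean
potential `ψ̄ = I₀·Ra + ψₐ`, and the excised-leaf decay
`E(t) = I₀·e^(−t/τ)` with `τ = C(Rc + Ra)`. A lumped single-capacitor
equivalent (`Rx = R/3`) and a water-sensitive stomatal extension
`Ra(W) = Rox + s(W₀ − W)` — which caps transpiration through
`ψₚ − ψₐ = (Rx+Rox)·Ia + C·Rx·s·Ia²` — round out the toolkit, along
with conversions among atmospheric water potential, relative humidity
and vapor pressure deficit.

## Worked example

The canonical uniform grass leaf: base at `ψ₀ = 0` (well watered),
moderately dry air at `ψₐ = −100 MPa` (≈48 % relative humidity), total
xylem resistance `R = 2` and xylem-to-air resistance `Ra = 50`
MPa·m²·s·mmol⁻¹, storage `C = 30 mmol·m⁻²·MPa⁻¹` behind `Rc = 1`:

```python
from leafhydraulics import *

params = UniformLeafParams(N=100, R=2.0, Ra=50.0, psi0=0.0, psi_a=-100.0,
                           Rc=1.0, C=30.0)
leaf = build_uniform_chain(params)
state = solve_steady(leaf)
print(f"mean xylem potential: {state.psi_bar:.3f} MPa")
print(f"total transpiration:  {state.E:.3f} mmol m-2 s-1")
print(f"tip potential:        {state.psi[-1]:.3f} MPa")

res = simulate(leaf, "steady", [(0.0, ExciseSource())],
               T=4590.0, dt=0.6, output_every=20)
tau_hat = fit_exponential(res.times, res.psi_bar, params.psi_a)
print(f"fitted decay constant: {tau_hat/60:.1f} min (closed form {30*51/60:.1f} min)")
```

prints

```
mean xylem potential: -1.312 MPa
total transpiration:  1.974 mmol m-2 s-1
tip potential:        -1.967 MPa
fitted decay constant: 25.5 min (closed form 25.5 min)
```

The potential tapers from 0 at the base to about −2 MPa at the tip —
the leaf tip is disproportionately disadvantaged even though the mean
stays near −1.3 MPa. After excision the whole water status decays
exponentially on the `C(Rc+Ra)` time scale: a bigger reservoir or a
more resistive storage pathway slows dehydration.

A CLI mirrors the library for shell use:

```bash
leafhydraulics convert --psia -100
# {"psi_a_MPa": -100.0, "RH_percent": 48.4, "VPD_kPa": 1.6363921480796562}
leafhydraulics scenario steady_state --config table1.json
leafhydraulics validate network.json
```

Scenario configs are flat JSON files of the whole-leaf keys
(`{"N": 100, "R": 2, "Ra": 50, "psi0": 0, "psi_a": -100, ...}`); see
`leafhydraulics scenario --help` for the four scenario names.

## Layout

| module | contents |
| --- | --- |
| `network` | domain types, chain/grid builders, validation, JSON I/O |
| `steady` | steady-state assembly/solve, derived currents and summaries |
| `transient` | rate-system assembly, Euler stepping, event schedules |
| `analytic` | continuum closed forms, decay constants, exponential fits |
| `lumped` | single-capacitor equivalent, stomatal sensitivity law |
| `environment` | ψₐ ↔ relative humidity ↔ VPD conversions |
| `scenarios` | scenario engine, stress-front tracking |
| `cli` | `leafhydraulics` command-line entry point |

See `docs/methods.md` for modelling assumptions, discretization choices
and limitations.
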