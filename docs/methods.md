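# Methods

## Model

A leaf blade is represented as an electrical-circuit analog of its
hydraulic architecture. Nodes carry xylem water potentials `ψᵢ` (MPa);
branches carry water fluxes (mmol·m⁻²·s⁻¹, per unit leaf area). Three
branch types attach to each node:

1. **Xylem segments** between neighbouring nodes, resistance
   `R_{ij}` (MPa·m²·s·mmol⁻¹). Flow is laminar, so flux is linear in
   the potential difference (Ohm's law / Hagen–Poiseuille).
2. **Transpiration branches** from each node to a common atmosphere
   wire at `ψₐ`, through `Rᵢ⁽ᵃ⁾` — the series resistance of the
   outside-xylem (mesophyll) liquid path and the stomatal vapor path.
   Closed stomata are `Rᵢ⁽ᵃ⁾ = ∞`, i.e. zero conductance; the branch is
   never deleted, so the no-flow limit is exact.
3. **Storage branches**: a linear capacitor `Cᵢ` (mmol·m⁻²·MPa⁻¹)
   behind resistance `Rᵢ⁽ᶜ⁾`, referenced to a common baseline osmotic
   potential `ψ_s` of the reservoir cells. The capacitor voltage is
   the cell turgor. `ψ_s` shifts reported turgor and stored water only;
   it never affects the dynamics of a linear constant capacitor, so it
   is an optional reporting-time parameter.

Water sources (the petiole/base supply) attach to chosen nodes through
a source resistance; their potential may be constant or an oscillating
waveform `A·cos(ω₀t + φ)`.

### Assumptions

- All resistances and capacitances are constant in time; in particular
  the stomatal resistance does not respond to water status (except in
  the lumped stomatal extension below). This isolates the role of
  capacitance in short-term transients, before stomatal regulation or
  embolism set in.
- Capacitors are linear (constant `C`), valid while reservoir cells
  stay above turgor loss.
- The atmosphere and the storage baseline are spatially uniform.

## Steady state

With no capacitor current, node potentials solve `B·ψ = a` where `B`
is the weighted graph Laplacian of the xylem edges plus the stomatal
(and source) conductances on the diagonal, and `a` collects boundary
injections `ψₐ/Rᵃ` and `ψ_p/R_p`. `B` is symmetric positive definite
whenever at least one node has a finite path to a boundary potential;
networks with no source and all stomata closed are rejected as
structurally singular. Solves are direct (dense symmetric LAPACK up to
2000 nodes, sparse LU beyond); the contract is machine-precision
accuracy, and tests hold solutions to a 1e-10 conservation residual.

## Transients

Differentiating the conservation law in time gives a rate system
`A·(dψ/dt) = b`: `A` adds the storage conductances `1/Rᶜ` to the
steady-state diagonal (symmetric positive definite always), and `b` is
the instantaneous conservation imbalance scaled by `1/(CᵢRᵢ⁽ᶜ⁾)`, plus
a `dψ_p/dt` injection for waveform sources. Integration is explicit
first-order (Euler), `ψ ← ψ + Δt·A⁻¹b`, with `A` factorized once per
event segment (Cholesky) and re-used across steps.

Numerical choices:

- **Step size.** Default `Δt = 0.6 s` (0.01 min). A guard computes the
  fastest single-node relaxation scale `CᵢRᵢ⁽ᶜ⁾·A_ii/(A_ii − 1/Rᵢ⁽ᶜ⁾)`
  (exact for a node against frozen neighbours; coupling shortens it by
  at most ~2×) and warns — optionally errors — when `Δt` exceeds a
  tenth of it. For the default grass-leaf parameters the fastest scale
  is ~30 s, so the default step has a wide margin.
- **Conservation by construction.** Capacitor currents are never
  integrated as separate state; they are reconstructed at reporting
  time as the conservation imbalance (inflow minus stomatal loss), so
  per-node mass balance is exact at every stored state and the global
  Kirchhoff balance `E + ΣIᶜ = influx` holds to round-off.
- **Events** (excision, atmosphere steps, source changes) fire at the
  first step boundary at-or-after their scheduled time. Potentials are
  continuous across events; currents may jump (e.g. `E` jumps by
  `Δψₐ/Ra` at a humidity step while `ψ̄` is continuous).
- **Storage-free nodes** (`C = 0` or `Rᶜ = ∞`) are rejected by the
  transient assembly, which divides by `C·Rᶜ`; the documented
  workaround is a small `C` with finite `Rᶜ` (at the cost of
  stiffness, which the step guard will flag).
- **Exponential fits** of relaxation series regress `log|ψ̄ − ψ̄_∞|`
  on time, with `ψ̄_∞` taken from the direct steady solve of the
  post-event network: a first pass over the whole series estimates the
  scale `τ₀`, a second pass restricted to `t ∈ [0.2τ₀, 2τ₀]` gives the
  reported constant. The window avoids both the early multi-mode
  transient and the late samples dominated by round-off. The fit is
  exact on noiseless exponentials; a non-monotone input triggers a
  quality warning with the log-linear R².

## Discretizing the uniform leaf

Whole-leaf combined parameters map to per-node values by the standard
series/parallel scaling: `R⁽ᵒ⁾ = R/N`, `R⁽ᵃ⁾ = N·Ra`, `R⁽ᶜ⁾ = N·Rc`,
`C⁽ᵒ⁾ = C/N`. The chain is **cell-centered**: node `i` sits at the
midpoint `x = (i−½)/N` of its cell, the base source connects to node 1
through half a cell of xylem (`R/2N`), interior nodes are one full
cell apart, and the tip is sealed (no onward edge — all water exits
through stomata or storage). This placement was chosen because it is
the finite-volume discretization of the continuum cable problem and is
second-order accurate: at `N = 100` the mean potential is within
5·10⁻⁵ relative of the closed form, versus ~1.5 % for the one-sided
variant with a full source segment, which would visibly bias two-digit
summaries. The source segment resistance is overridable
(`build_uniform_chain(..., source_R=...)`) for users who want the
one-sided convention.

The continuum closed forms (steady profile, base influx, mean
potential, excised decay) were derived from the cable equation with a
Dirichlet base and sealed tip; they are cross-checked in the tests
against fine discretizations (`N = 2000`) rather than assumed.

## Lumped model and stomatal sensitivity

The lumped equivalent collapses the chain to one node at the mean
xylem potential: source through `Rx = R/3`, transpiration through
`Ra`, storage `C` behind `Rc`. `R/3` is exact in the weak-leak limit
`R/Ra → 0` (the factor a distributed leak presents to its mean), and
agreement with the spatial model improves monotonically as `Ra` grows;
at the default parameters (`R/Ra = 0.04`) lumped and spatial steady
states agree to better than 0.5 %. The lumped transient is a single
linear ODE and is advanced with its exact per-segment exponential
solution (no discretization error); the excised time constant
`C(Rc+Ra)` is therefore reproduced to round-off.

The stomatal extension makes `Ra` depend linearly on stored water,
`Ra(W) = Rox + s(W₀ − W)`, with the linear capacitor `V = W/C`. `W₀`
is referenced to the zero-flow state (`ψ_x = ψ_p`): with that
reference the baseline osmotic potential cancels, the steady state
closes into a scalar quadratic in the xylem drawdown `D = ψ_p − ψ_x`,

    s·C·D² + (Rox + Rx)·D − Rx·(ψ_p − ψ_a) = 0,

and the root continuous in `s` with the `s = 0` solution (equivalently
the one with `Ia ≥ 0`, `W ≤ W₀`) is the physical one. Substituting
back gives the *exact* polynomial relation
`ψ_p − ψ_a = (Rx+Rox)·Ia + C·Rx·s·Ia²` — the quadratic term is how
stomatal sensitivity to water content caps transpiration under rising
evaporative demand. The looser "well-watered" reference for `W₀` would
perturb the linear coefficient but not the quadratic one.

## Environment conversions

`ψₐ = (R̄T/v)·ln(RH)` with `R̄ = 8.3145 J·mol⁻¹·K⁻¹`, `T = 298.15 K`
and `v = 18·10⁻⁶ m³·mol⁻¹` (so `R̄T/v ≈ 137.7 MPa`), and
`VPD = (1−RH)·P` with `P = 3.17 kPa` at room temperature. Temperature
and saturation pressure are configurable; RH is a fraction internally
and a percentage only in reports.

## Scenarios and stress front

The scenario engine wires these pieces into four canned experiments
(steady state, excision, humidity step, spatial snapshots) driven by a
flat JSON config. The stress front `x*(t)` is the basal-most position
where the local potential falls below a damage threshold
(default −2.5 MPa, below which embolism and tissue damage are
expected), located by linear interpolation between the straddling
nodes; it is defined only for chain topologies. During a drying step
the front first appears near the tip and moves baseward — the tip is
sacrificed long before the leaf-average potential looks dangerous,
which is the central caution the spatial model adds over lumped ones.

Scenario defaults: `N = 100` nodes, `Δt = 0.6 s`, horizon `3·C(Rc+Ra)`
unless overridden, outputs every 10 steps. These sizes resolve all
printed summaries to their displayed precision while keeping any
scenario in the low seconds on one core.

## What the fixtures do and do not show

All inputs are synthetic: uniform chains built from whole-leaf
parameters chosen to mimic a well-watered grass leaf in moderately dry
air (potential drop of ~2 MPa base-to-tip, transpiration ~2
mmol·m⁻²·s⁻¹, dehydration time constants of tens of minutes to hours).
Passing tests therefore demonstrate the solvers' correctness against
closed forms and brute-force oracles, and the internal consistency of
the circuit analog — not agreement with any particular measured leaf.
Real leaves have hierarchical venation, spatially varying and
nonlinear stomatal behaviour, vulnerability to embolism, and variable
capacitance; none of these are modelled here (constant `Ra` is a
deliberate idealization for short-term dynamics), though heterogeneous
chains and 2-D grids with per-node parameters provide the hooks for
spatial variation.

## Known limitations

- Explicit first-order stepping: accuracy is `O(Δt)`; halving the step
  halves trajectory errors. The default step resolves the default
  parameter regime; very small `C·Rc` products require smaller steps
  (the guard warns).
- The oscillating-source case is handled numerically only; no modal
  closed form is provided.
- Stress-front tracking assumes a chain; on grids the stressed region
  is not a single interval.
- The stomatal law is the lumped model's; the spatial solver keeps
  `Ra` constant.
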