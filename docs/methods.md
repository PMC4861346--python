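# Methods

## Model and assumptions

`pumpleak` implements the minimal pump-leak description of monovalent
ion homeostasis in a single animal cell. The state is the set of
intracellular concentrations (Na⁺, K⁺, Li⁺, Cl⁻, mM in cell water), the
cell water volume `V`, and a membrane-impermeant intracellular osmolyte
pool of amount `A` and mean valence `z`. Two algebraic constraints are
enforced continuously: macroscopic electroneutrality (the fixed charge
`z·A/V` balances the ionic charge difference) and osmotic balance (total
internal osmolarity equals the external osmolarity `S_o`; osmotic
coefficients are taken as 1). `z` and `A` are computed once from the
initial state and never updated — the impermeant pool neither leaks nor
is metabolized on the timescales modeled. `A` is normalized to 1 mmol;
only `V/A` and `A/V` are physically meaningful, and all fluxes are per
ml of cell water.

Transport is divided thermodynamically into five pathway types, each
with a single rate coefficient and no saturation:

* **Channels** — constant-field (Goldman-type) fluxes
  `p·u·(Cᵢeᵘ − Cₒ)/g` for cations and `p_Cl·u·(Clᵢ − Clₒeᵘ)/g` for the
  anion, `g = 1 − eᵘ`. Both are positive inward and vanish exactly at
  the Nernst equilibrium of the ion.
* **Na/K pump** — efflux `−β[Na]ᵢ`, K⁺ return `β[Na]ᵢ/γ`; electrogenic
  for γ > 1. A parallel Li/K mode (`α`) covers the pump's weak handling
  of Li⁺.
* **Electroneutral cotransporters** NC, KC, LC (1:1 with Cl⁻) and NKCC,
  LKCC (1:1:2) — bilinear in the concentration products, zero at equal
  inside/outside products.
* **Li/Na countertransport** (LN) — `k_P([Na]ₒ[Li]ᵢ − [Na]ᵢ[Li]ₒ)`, the
  secondary-active Li⁺ extrusion pathway.
* **Coupled self-exchange** (Na/Na, Cl/Cl) — `kp_X·Cₒ·Cᵢ` each way;
  contributes to unidirectional traffic (tracer turnover) but never to a
  net flux, so it is handled in the flux-accounting and tracer layers
  rather than the dynamical core. A `kpCl` hook exists but no default
  value is shipped.

Temperature is fixed at 37 °C (RT/F = 26.7 mV); this is not configurable
in v1. Ca²⁺/Mg²⁺ and pH dynamics are out of scope.

## Membrane potential

The dimensionless potential `u` is the root of the total charge-flux
balance: the sum of the four channel fluxes (anion with opposite sign)
minus the electrogenic pump term `(β[Na]ᵢ + α[Li]ᵢ)(1 − 1/γ)`. This is
algebraically identical to the classical transcendental potential
equation obtained by eliminating the cotransporters from the charge
derivative, but remains finite at `u = 0` (the traditional form divides
the pump term by `u`). The factor `u/(1 − eᵘ)` switches to a three-term
Taylor branch for |u| < 1e−6; the branch agrees with the closed form to
6 significant figures at the switchover.

The solver runs a 200-interval sign scan over U ∈ [−173, +5] mV followed
by Brent refinement (`xtol` 1e−14 in `u`, i.e. ≪1e−9 mV); inside the
integrator a secant iteration warm-started from the previous step's root
is tried first and falls back to the scan whenever it leaves the window
or fails the residual check |Φ| < 1e−9. No sign change in the window
raises the `RANGE LIMIT` diagnostic. On every fixture state the root is
unique (property-tested with a 400-point scan).

## Integration

Explicit Euler with `dt = 0.1 min` by default. Each step solves the
potential, advances the four ion contents, then recomputes the volume
from the osmotic constraint, `V = (Σ contents + A)/S_o`; contents are
never renormalized — electroneutrality is preserved automatically
because the signed sum of the content derivatives vanishes at the solved
potential (drift < 1e−6 relative over a full run, property-tested).
The step size is inferred from the original report cadence (output every
50 min at `hp = 500` steps per output); halving it moves the reference
balanced state by < 2e−4 mM, far inside the 0.01 mM acceptance band.

A run starts from a DATAP parameter set. The `kv` adjustment models the
instantaneous osmotic water shift on a medium switch: internal
concentrations are multiplied by `kv = S_o(new)/S_o(old)`, then `z` and
`V/A` are recomputed. Physically impossible inputs (internal osmolarity
≥ external after adjustment) raise `BAD INITIAL DATA`; internal Na
falling below 0.1 mM during a run raises `LOW SODIUM` (both messages
verbatim from the original program, with the failure time attached).
Mid-run medium changes are expressed by chaining runs: re-initialize
with the current internal state and a new `kv`.

Two stopping rules coexist. The library default detects the balanced
state when every instantaneous concentration derivative falls below
`balance_tol = 0.005 mM·min⁻¹` (the final derivatives of the reference
run are 0.0001–0.003). Reproduction runs instead use the fixed schedule
of the original report — 10 output rows of 500 steps, i.e. 500 min —
with balance detection off: the published Li-distribution and
sensitivity tables correspond to the 500-min states of that fixed
schedule, not to tolerance-converged states (at 10 mM external Li the
fully converged discrimination coefficient is ~1% lower than the
printed value, while the 500-min state matches it to 0.1%). Trajectory
rows carry instantaneous analytic derivatives; interval-averaged slopes
can be formed from adjacent rows if preferred — the two differ visibly
early in a transient.

## Flux accounting

`unidirectional_decomposition` splits every pathway into the two
additive terms of its rate law: for channels the term carrying the
external concentration is the influx (the voltage factor `u/(1 − eᵘ)` is
negative-definite, which makes the split sign-definite for either sign
of `u`); for carriers the outside product is the influx; the pump
contributes pure Na⁺/Li⁺ efflux and pure K⁺ influx. Influx + efflux =
net holds exactly in all 36 cells by construction. OSOR is the
pump-mediated K⁺ influx over the summed K⁺ influx of all other pathways.
Turnover per ion is the influx sum plus any coupled self-exchange; at a
balanced state it equals the efflux sum and, divided by the internal
concentration, predicts the tracer equilibration rate coefficient.

## Tracer kinetics

Tracer simulations run on a frozen balanced background: at trace level
the tracer cannot perturb the bulk state, the tracer balance is linear,
and the curve is exactly monoexponential with rate
`k = α + p·(−h)·eᵘ + i_C·[Cl]ᵢ + kp·[Na]ₒ` (efflux; the influx rate
constant is the mirrored outside form). A full-model mode integrates the
tracer through the Li slot of the complete system instead; the two agree
within 2% at trace loads and the frozen mode is numerically cleaner.
The tracer's pump term defaults to the parent ion's (`α = β` for ²²Na);
`include_pump=False` exposes the pump-free variant, since the original
description only states "parameters similar to those of the Na⁺
carrier". Loss curves are fitted log-linearly, gain curves by nonlinear
least squares on `y_∞(1 − e^{−kt})`; the 3-point design (5/10/20 min) is
supported. `estimate_kp_na` brackets and bisects the simulated-rate
mismatch to 1e−6 in `kp`.

## Inverse problem

`fit_balanced` minimizes the relative residual between computed and
measured balanced observables (concentrations, (V/A)×1000, OSOR) over a
chosen subset of coefficients, using Nelder–Mead on multipliers of the
initial guesses with bound clipping (small dimension, smooth forward
map, no gradients; relative tolerance 1e−4). Runs that fail to balance
return a large sentinel residual. Fits with fewer targets than free
parameters are flagged non-identifiable — the balanced [Li]ᵢ alone
admits a one-parameter family of (ilc, kp) pairs; `resolve_ilc_kp`
breaks the degeneracy by jointly fitting the balanced value and a
transient [Li]ᵢ(t) curve, recovering synthetic truth pairs within 5%.
The 5% acceptance band for recovery is this package's convention; the
original trial-and-error protocol stated none. One caveat found while
validating sensitivities: near the reference point the balanced K⁺
*concentration* is nearly flat in `pk` (the extra leak shrinks the cell
and re-concentrates K⁺), whereas the K⁺ *content* per impermeant
(k·V/A) falls monotonically — sensitivity checks should use contents.

## Fixtures, file formats, sizes

The shipped fixtures are the published parameter sets: the reference
system, the ouabain pump-block set, the Na→Li substitution family, the
return-to-Na set, and the Li-preload recovery scenarios. Media with X mM
LiCl added to Li-free RPMI (osmolarity 310 mM) use `l0 = X`,
`cl0 = 116 + X`, `kv = (310 + 2X)/310`; this rule reproduces the
reference `kv = 1.032` at X = 5 and the published Li-distribution
predictions at 1–10 mM to <1%. DATAP files are whitespace-delimited
(24 values, fixed order, optional headers); RESP files mirror the
original three-part report (parameter echo with computed `z` and final
`A/V`; trajectory; flux matrix to 4 decimals with the OSOR line) and
round-trip through `read_resp`. All validation inputs are printed
parameter tables, so tests and the acceptance script generate everything
programmatically; a 500-min reference run costs ~5000 Euler steps and
well under a second.

## Known limitations

First-order rate laws ignore transporter saturation, so predictions
degrade far from the fitted operating point. Trace-level tracer theory
breaks down for loads that are not small against the parent ion.
The explicit Euler scheme is first-order; `dt` must resolve the fastest
relaxation (the default 0.1 min is ample for the shipped parameter
sets). The synthetic fixtures emulate printed parameter sets, not raw
measurements: passing tests shows the computational pipeline reproduces
the model's published behavior, not that the model describes any
particular new cell type.
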