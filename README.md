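# pumpleak

Whole-cell pump-leak flux balance for monovalent ions (Na⁺, K⁺, Li⁺, Cl⁻)
with Li/Na countertransport and coupled self-exchange.

Monovalent ion fluxes across an animal cell membrane are strongly
interdependent: electroneutrality and osmotic balance couple every
pathway to every other, so individual unidirectional fluxes cannot be
read off measurements directly. `pumpleak` computes the whole-cell flux
balance — balanced (steady) states, transients, membrane potential, cell
water — and decomposes the traffic of each ion into net and
unidirectional fluxes per pathway. It is aimed at cell physiologists who
measure ion concentrations, Rb⁺(K⁺) influx and tracer equilibration
rates and want to turn those into rate coefficients for the pump,
channels and co-/countertransporters (the motivating data set is the
human lymphoid cell line U937, where Li⁺ serves as a tracer analogue of
Na⁺).

## Model

The cell holds intracellular concentrations `[Na]ᵢ, [K]ᵢ, [Li]ᵢ, [Cl]ᵢ`
(mM), water volume `V`, and a fixed amount `A` of membrane-impermeant
osmolytes with mean valence `z`. Two constraints hold at all times:

```
[Na]ᵢ + [K]ᵢ + [Li]ᵢ − [Cl]ᵢ + z·A/V = 0                    (electroneutrality)
[Na]ₒ + [K]ₒ + [Li]ₒ + [Cl]ₒ + [B]ₒ = Σ[ion]ᵢ + A/V         (osmotic balance)
```

Ion contents evolve by first-order rate laws, e.g. for Na⁺:

```
d([Na]ᵢV)/dt = V { p_Na·u·([Na]ᵢeᵘ − [Na]ₒ)/g − β[Na]ᵢ + J_NC + J_NKCC + J_LN }
```

with `u = U·F/RT` (RT/F = 26.7 mV at 37 °C), `g = 1 − eᵘ`, the
Goldman-type constant-field term for channels (the Cl⁻ channel uses the
anion form `p_Cl·u·([Cl]ᵢ − [Cl]ₒeᵘ)/g`), the electrogenic Na/K pump
`−β[Na]ᵢ` returning K⁺ at `β[Na]ᵢ/γ` (stoichiometry γ = 1.5; an optional
Li/K mode uses α), and bilinear electroneutral carriers
`J_NC = i_NC([Na]ₒ[Cl]ₒ − [Na]ᵢ[Cl]ᵢ)`, analogously KC, LC, NKCC, LKCC,
and the Li/Na countertransporter `J_LN = k_P([Na]ₒ[Li]ᵢ − [Na]ᵢ[Li]ₒ)`.
The membrane potential is the root of the total charge-flux balance
(equivalent to the classical transcendental equation, but finite at
u = 0), solved on U ∈ [−173, +5] mV at every Euler step; volume follows
from the osmotic constraint.

Each pathway flux splits exactly into a unidirectional influx and
efflux (the two additive terms of its rate law). Coupled self-exchange
(Na/Na, Cl/Cl) — `J = kp·Cₒ·Cᵢ` — adds to both directions equally, so it
is invisible in the balanced state but dominates tracer turnover; the
`tracer` module simulates ²²Na-style equilibration curves and estimates
`kpNa` from a measured rate coefficient.

## Worked example

The reference parameter set (U937 cells in RPMI + 5 mM LiCl) ships as a
fixture:

```python
import pumpleak as pl

datap = pl.fixtures.reference()
system = pl.initialize_run(datap, balance_tol=None, max_outputs=10)
traj = pl.run(system)                      # 500 min, dt = 0.1 min
cell = traj.cell
print(f"na {cell.na:.1f}  k {cell.k:.1f}  l {cell.l:.3f}  cl {cell.cl:.1f}"
      f"  U {traj.potential.U:.1f} mV")
table = pl.unidirectional_decomposition(cell, traj.medium, traj.params,
                                        traj.potential.u)
print(f"OSOR {pl.osor(table):.2f}   Li turnover "
      f"{pl.turnover_flux(table)['Li']:.4f}")
```

prints

```
na 38.6  k 155.2  l 4.375  cl 72.1  U -47.5 mV
OSOR 3.53   Li turnover 0.1849
```

i.e. starting from the kv-adjusted Li-free state the cell settles at
38.6 mM Na⁺, 155.2 mM K⁺, 4.375 mM Li⁺ and 72.1 mM Cl⁻ at −47.5 mV; the
pump carries 3.53× more K⁺ inward than all passive pathways combined,
and total unidirectional Li⁺ traffic is 0.185 µmol·min⁻¹·(ml cell
water)⁻¹ — which at [Li]ᵢ = 4.4 mM corresponds to the observed Li⁺
equilibration rate of 0.042 min⁻¹.

The same run from the shell, reading/writing the plain-text DATAP/RESP
formats:

```
$ pumpleak run --datap DATAP.txt --tol 0 --max-outputs 10 --out RESP.txt
$ pumpleak balance --datap DATAP.txt
t = 400 min (balanced)
na 38.6  k 155.3  l 4.383  cl 71.7 mM
U -47.6 mV   (V/A)x1000 20.01   z -2.53
OSOR 3.53
```

`pumpleak fluxes` prints the full net/influx/efflux matrix (optionally
with Na/Na and Cl/Cl self-exchange), `pumpleak tracer` simulates and
fits tracer curves, and `pumpleak fit` solves the inverse problem for
selected coefficients. Exit code 2 signals the model diagnostics
`BAD INITIAL DATA`, `RANGE LIMIT` and `LOW SODIUM`.

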