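# gatekit

Quantitative analysis of a hydrophobically gated, Ca²⁺-activated chloride
channel: equilibrium gating models, ion-permeation fits and thermodynamic
mutant-cycle analysis for patch-clamp concentration-response and
current-voltage data.

## The problem

The anion conduction path of the channel is closed by a gate of three
juxtaposed isoleucines (positions 550, 551 and 641) whose apolar side
chains exclude water and ions. Mutagenesis that shrinks the side-chain
volume (Ile→Val removes one methyl group, Ile→Ala three) or increases its
polarity left-shifts the Ca²⁺ EC₅₀ and can produce basal (ligand-free)
activity. `gatekit` turns such datasets into energies:

* **Hill fits** of normalized concentration-response relations,
  I/I_max = 1 / (1 + (EC₅₀/[Ca²⁺])ʰ), give per-mutant EC₅₀ and Hill
  coefficient with Jacobian-based 95% confidence intervals.

* **A minimal n-barrier permeation model** describes instantaneous I-V
  relations of the open pore. With σ_h and σ_β the crossing rates at the
  middle and innermost barriers relative to the outermost,

      I = zFA e^{zFV/2nRT} (c_i − c_o e^{−zFV/RT}) /
          (e^{−zFV(n−1)/nRT} + (1/σ_h)(1 − e^{−zFV(n−2)/nRT})/(e^{zFV/nRT} − 1) + 1/σ_β)

  and ΔE_a(σ) = −RT ln σ converts fitted rates into barrier-energy
  differences. Rectification diagnoses where along the pore a mutation
  raises the barrier.

* **A six-state MWC gating model** — closed and open conformations joined
  by two identical Ca²⁺-binding steps with constants K_d(C), K_d(O), and
  gating constants linked by microscopic reversibility,
  L₀ = L₂ (K_d(O)/K_d(C))² — predicts the normalized response including
  sub-conductance levels (i, j, k) at occupancy 0, 1, 2. Chemical
  perturbations act on L₂ only:

      L₂(Δn_Me)  = L₂WT · e^{−Δn_Me ΔG_Me / RT}          (methyl volume)
      L₂(ΔΔG_h)  = L₂WT · e^{δ ΔΔG_hydration / RT}       (hydration energy)
      L₂,mut     = L₂WT · e^{−ΔG_mut / RT}               (mutant-specific)

  A global fit of the methyl and hydration EC₅₀ series with shared
  binding constants yields the per-methyl-group energy ΔG_Me and the
  hydration fraction δ.

* **Mutant cycles**: ΔG = −RT ln L per construct; non-additivity of
  double mutants gives the coupling energy ΔΔΔG, and its change upon a
  third mutation the triadic term ΔΔΔΔG, with standard errors propagated
  in quadrature and two-sided one-sample t-tests against zero.

A seeded synthetic-data module generates dose-response panels and I-V
curves with the statistical structure of averaged inside-out patch
recordings (per-point mean ± SEM over replicate patches), so every stage
of the pipeline is testable without experimental data.

## Worked example

```bash
python examples/03_chemical_gating_fit.py
```

```
per-methyl energy : 0.852 kcal/mol (95% CI 0.786-0.917; generated with 0.830)
hydration fraction: 0.379 (95% CI 0.345-0.413; generated with 0.370)
shared Kd(C)      : 20.43 µM   (closed-state affinity)
shared Kd(O)      : 0.206 µM  (open-state affinity)
```

A 27-construct Ile/Val/Ala panel plus a polar-substitution series is
generated with 0.05-decade EC₅₀ scatter and refitted blind: each buried
methyl group stabilises the closed state by ~0.8 kcal/mol, and roughly a
third of a substitution's hydration-energy change is transduced into the
opening equilibrium — both inside their confidence intervals. The other
scripts in `examples/` cover Hill fitting, permeation/I-V analysis,
mutant cycles and the end-to-end pipeline; the same stages are available
from the shell via `gatekit simulate|fit-hill|fit-iv|fit-gating|cycles|run-all`.

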