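"""Global MWC fit of the methyl-volume and hydration EC50 series.

The 27-construct Ile/Val/Ala panel titrates the hydrophobic volume of the
three gate residues (each removed methyl group destabilises the closed
state by ΔG_Me), and a polar-substitution series titrates hydration
energy (a fraction δ of which acts on the gating equilibrium).  Both
series are fitted jointly with shared binding constants K_d(C), K_d(O).
"""

from gatekit import fit_chemical_global
from gatekit.synthetic import SimulationScenario, generate_triad_panel

scenario = SimulationScenario(seed=3)  # truth: ΔG_Me = 0.83, δ = 0.37
panel = generate_triad_panel(scenario)

fit = fit_chemical_global(
    panel.methyl_pairs(), panel.hydration_pairs(), l2_wt=scenario.l2_wt
)

lo_m, hi_m = fit.fit.ci_of("dg_me")
lo_d, hi_d = fit.fit.ci_of("delta")
print(f"per-methyl energy : {fit.dg_me:.3f} kcal/mol "
      f"(95% CI {lo_m:.3f}-{hi_m:.3f}; generated with 0.830)")
print(f"hydration fraction: {fit.delta:.3f} "
      f"(95% CI {lo_d:.3f}-{hi_d:.3f}; generated with 0.370)")
print(f"shared Kd(C)      : {fit.kd_c:.2f} µM   (closed-state affinity)")
print(f"shared Kd(O)      : {fit.kd_o:.3f} µM  (open-state affinity)")
print()
print("Each methyl group buried at the gate stabilises the closed state by")
print("~0.8 kcal/mol; about a third of a substitution's hydration-energy")
print("change is transduced into the opening equilibrium.")
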