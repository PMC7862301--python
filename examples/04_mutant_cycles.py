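"""Double-mutant cycle analysis of the gate residues.

Gating free energies ΔG_mut of the four corners of a cycle (WT, the two
valine singles, the double) are fitted from full concentration-response
curves with shared binding constants.  Non-additivity — the coupling
energy ΔΔΔG — measures the energetic interaction between the two
positions; here a +0.5 kcal/mol interaction between residues 550 and 641
is built into the synthetic data and recovered.
"""

from scipy import stats

from gatekit import Cycle, Measurement, coupling_energy, fit_mutant_deltaG, one_sample_t
from gatekit.datatypes import MutantSpec
from gatekit.synthetic import SimulationScenario, generate_dose_response_panel

scenario = SimulationScenario(seed=4, coupling={(550, 641): 0.5})
specs = [
    MutantSpec(),                          # WT
    MutantSpec(residues=("V", "I", "I")),  # I550V
    MutantSpec(residues=("I", "I", "V")),  # I641V
    MutantSpec(residues=("V", "I", "V")),  # I550V/I641V
]
curves, _ = generate_dose_response_panel(scenario, panel=specs)
fits = fit_mutant_deltaG(curves, scenario.kd_c, scenario.kd_o, scenario.l2_wt)

for mid, fit in fits.items():
    print(f"dG_mut({mid:12s}) = {fit.param('dg_mut'):+.3f} "
          f"± {fit.se_of('dg_mut'):.3f} kcal/mol")

corners = {
    "wt": Measurement(fits["WT"].param("dg_mut"), fits["WT"].se_of("dg_mut")),
    "x": Measurement(fits["I550V"].param("dg_mut"), fits["I550V"].se_of("dg_mut")),
    "y": Measurement(fits["I641V"].param("dg_mut"), fits["I641V"].se_of("dg_mut")),
    "xy": Measurement(fits["I550V/I641V"].param("dg_mut"),
                      fits["I550V/I641V"].se_of("dg_mut")),
}
coupling = coupling_energy(Cycle.from_corners(corners))
dof = min(f.dof for f in fits.values())
test = one_sample_t(coupling.value, coupling.se, dof)

print(f"\ncoupling energy 550-641: {coupling.value:+.3f} ± {coupling.se:.3f} "
      f"kcal/mol (injected +0.500)")
print(f"one-sample t-test vs 0 : t = {test.t:.2f}, p = {test.p:.2g}")
print("\nA coupling indistinguishable from zero would mean the two residues")
print("stabilise the closed state independently; a significant positive value")
print("indicates they act cooperatively, as engineered here.")
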