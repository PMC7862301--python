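"""Seeded generators of synthetic patch-clamp data.

The generators emulate the statistical structure of averaged inside-out
patch recordings of a Ca²⁺-activated chloride channel: sigmoidal
normalized concentration-response relations per mutant (with basal
activity for strongly activating mutants), rectifying instantaneous I-V
curves, and per-point Gaussian measurement scatter reported as
mean ± SEM over replicate patches.  Every draw comes from one seeded RNG
stream per scenario, so a fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import Constants, DEFAULT_CONSTANTS, GATE_POSITIONS, WT_RESIDUE
from .datatypes import (
    ChemicalPerturbation,
    DoseResponseCurve,
    DoseResponsePoint,
    IVCurve,
    MutantSpec,
    annotate_mutant,
)
from .mwc import (
    ConductanceLevels,
    DEFAULT_LEVELS,
    MWCParams,
    l2_from_hydration,
    l2_from_methyl,
    l2_from_mutant,
    model_ec50,
    normalized_response,
)
from .permeation import PermeationParams, barrier_current

#: response scatter is truncated at these physical bounds
RESPONSE_BOUNDS = (-0.05, 1.1)

#: polar/small residues of the default hydration-titration series
HYDRATION_RESIDUES = ("M", "C", "G", "S", "N")


def default_ca_grid() -> np.ndarray:
    """0, 13 log-spaced points over 0.02–20 µM, and 1000 µM (saturating)."""
    return np.concatenate([[0.0], np.geomspace(0.02, 20.0, 13), [1000.0]])


def default_voltage_grid() -> np.ndarray:
    """−100 to +100 mV in 20 mV steps."""
    return np.arange(-100.0, 101.0, 20.0)


def triad_specs() -> list[MutantSpec]:
    """The full 27-construct I/V/A substitution panel (WT included)."""
    residues = ("I", "V", "A")
    return [
        MutantSpec(residues=(a, b, c))
        for a in residues
        for b in residues
        for c in residues
    ]


def hydration_specs(residues=HYDRATION_RESIDUES) -> list[MutantSpec]:
    """Single polar substitutions at each gate position, plus WT."""
    specs = [MutantSpec()]
    for idx in range(len(GATE_POSITIONS)):
        for aa in residues:
            res = [WT_RESIDUE] * len(GATE_POSITIONS)
            res[idx] = aa
            specs.append(MutantSpec(residues=tuple(res)))
    return specs


@dataclass
class SimulationScenario:
    """Ground truth and sampling plan of one synthetic study.

    Defaults reproduce the study conditions: per-methyl gating energy
    0.83 kcal/mol, hydration fraction 0.37, L₂WT = 10 (saturating open
    probability ≈ 0.91; placeholder for the noise-analysis estimate),
    log₁₀-EC50 scatter of 0.05 decades, response scatter sd 0.03 over 6
    patches per point.
    """

    kd_c: float = 20.0  # µM
    kd_o: float = 0.2  # µM
    l2_wt: float = 10.0
    dg_me: float = 0.83  # kcal/mol per methyl group
    delta: float = 0.37  # hydration fraction
    dg_mut: dict[str, float] = field(default_factory=dict)
    levels: dict[str, ConductanceLevels] = field(default_factory=dict)
    coupling: dict[tuple[int, int], float] = field(default_factory=dict)
    ca_grid: np.ndarray = field(default_factory=default_ca_grid)
    voltage_grid: np.ndarray = field(default_factory=default_voltage_grid)
    noise_sd_response: float = 0.03
    noise_frac_current: float = 0.02
    ec50_log10_sd: float = 0.05
    n_patches: int = 6
    seed: int = 0
    constants: Constants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if min(self.noise_sd_response, self.noise_frac_current, self.ec50_log10_sd) < 0:
            raise ValueError("noise magnitudes must be >= 0")
        self.ca_grid = np.asarray(self.ca_grid, dtype=float)
        self.voltage_grid = np.asarray(self.voltage_grid, dtype=float)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    # -- ground-truth composition ------------------------------------------

    def perturbation(
        self, spec: MutantSpec, series: str = "methyl"
    ) -> ChemicalPerturbation:
        return annotate_mutant(spec, require_methyl=(series == "methyl"))

    def extra_dg(self, spec: MutantSpec) -> float:
        """Mutant-specific energy: explicit ΔG_mut plus injected pairwise
        coupling terms for constructs where both partners are mutated."""
        dg = self.dg_mut.get(spec.mutant_id, 0.0)
        mutated = {
            pos for pos, aa in zip(GATE_POSITIONS, spec.residues) if aa != WT_RESIDUE
        }
        for pair, energy in self.coupling.items():
            if set(pair) <= mutated:
                dg += energy
        return dg

    def l2_of(self, spec: MutantSpec, series: str = "methyl") -> float:
        """Ground-truth L₂, composed multiplicatively.

        ``series`` selects the chemistry route: the hydrophobic-volume
        series scales L₂ with the methyl count, the polarity series with
        the hydration-energy change.
        """
        pert = self.perturbation(spec, series)
        if series == "methyl":
            l2 = l2_from_methyl(pert.delta_n_me, self.dg_me, self.l2_wt, self.constants)
        elif series == "hydration":
            l2 = l2_from_hydration(pert.ddg_hydration, self.delta, self.l2_wt, self.constants)
        else:
            raise ValueError(f"unknown series {series!r}")
        extra = self.extra_dg(spec)
        if extra:
            l2 = l2_from_mutant(extra, l2, self.constants)
        return l2

    def mwc_params(self, spec: MutantSpec, series: str = "methyl") -> MWCParams:
        return MWCParams(self.kd_c, self.kd_o, self.l2_of(spec, series))

    def levels_of(self, spec: MutantSpec) -> ConductanceLevels:
        return self.levels.get(spec.mutant_id, DEFAULT_LEVELS)

    def truth(self) -> dict:
        return {
            "kd_c": self.kd_c,
            "kd_o": self.kd_o,
            "l2_wt": self.l2_wt,
            "dg_me": self.dg_me,
            "delta": self.delta,
            "dg_mut": dict(self.dg_mut),
            "coupling": {f"{a}-{b}": v for (a, b), v in self.coupling.items()},
            "noise_sd_response": self.noise_sd_response,
            "ec50_log10_sd": self.ec50_log10_sd,
            "n_patches": self.n_patches,
            "seed": self.seed,
        }


def generate_dose_response_panel(
    scenario: SimulationScenario,
    panel: list[MutantSpec] | None = None,
    series: str = "methyl",
    rng: np.random.Generator | None = None,
) -> tuple[list[DoseResponseCurve], dict]:
    """Per-mutant averaged concentration-response curves with SEM.

    Each point is the mean of ``n_patches`` i.i.d. Gaussian replicates of
    the analytic response, truncated at physical bounds; SEM is the sample
    standard error.  With zero noise the curves equal the model exactly.
    """
    panel = panel if panel is not None else triad_specs()
    rng = rng if rng is not None else scenario.rng()
    curves = []
    truth = scenario.truth()
    truth["mutants"] = {}
    for spec in panel:
        params = scenario.mwc_params(spec, series)
        levels = scenario.levels_of(spec)
        clean = np.asarray(
            normalized_response(scenario.ca_grid, params, levels), dtype=float
        )
        points = []
        for ca, mu in zip(scenario.ca_grid, clean):
            if scenario.noise_sd_response > 0:
                draws = mu + scenario.noise_sd_response * rng.standard_normal(
                    scenario.n_patches
                )
                draws = np.clip(draws, *RESPONSE_BOUNDS)
                mean = float(np.mean(draws))
                sem = float(np.std(draws, ddof=1) / np.sqrt(scenario.n_patches))
            else:
                mean, sem = float(mu), 0.0
            points.append(
                DoseResponsePoint(ca=ca, response=mean, sem=sem,
                                  n_patches=scenario.n_patches)
            )
        curves.append(DoseResponseCurve(spec.mutant_id, points))
        truth["mutants"][spec.mutant_id] = {
            "l2": scenario.l2_of(spec, series),
            "dg_total": scenario.extra_dg(spec),
            "series": series,
        }
    return curves, truth


def generate_iv(
    scenario: SimulationScenario,
    params: PermeationParams,
    condition: str,
    mutant_id: str = "synthetic",
    rng: np.random.Generator | None = None,
) -> IVCurve:
    """Barrier-model I-V on the voltage grid with multiplicative noise."""
    rng = rng if rng is not None else scenario.rng()
    v = scenario.voltage_grid
    current = np.asarray(barrier_current(v, params), dtype=float)
    if scenario.noise_frac_current > 0:
        current = current * (
            1.0 + scenario.noise_frac_current * rng.standard_normal(len(v))
        )
    return IVCurve(mutant_id, condition, v, current)


@dataclass
class TriadPanel:
    """EC50 panels of the two chemistry titrations plus ground truth."""

    methyl_series: list[tuple[str, float, float]]  # (mutant_id, Δn_Me, EC50 obs)
    hydration_series: list[tuple[str, float, float]]  # (mutant_id, ΔΔG_hyd, EC50 obs)
    truth: dict

    def methyl_pairs(self) -> list[tuple[float, float]]:
        return [(dn, ec) for _, dn, ec in self.methyl_series]

    def hydration_pairs(self) -> list[tuple[float, float]]:
        return [(ddg, ec) for _, ddg, ec in self.hydration_series]


def generate_triad_panel(
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
) -> TriadPanel:
    """EC50s of the 27-construct I/V/A panel and the hydration series.

    True EC50s come from the model half-crossing on the composed L₂;
    observed EC50s carry seeded log-normal scatter of ``ec50_log10_sd``
    decades, mimicking patch-to-patch EC50 variability.
    """
    rng = rng if rng is not None else scenario.rng()
    truth = scenario.truth()
    truth["ec50_true"] = {}

    def one_series(specs, series):
        out = []
        for spec in specs:
            pert = scenario.perturbation(spec, series)
            x = pert.delta_n_me if series == "methyl" else pert.ddg_hydration
            ec50 = model_ec50(scenario.mwc_params(spec, series),
                              scenario.levels_of(spec))
            obs = ec50 * 10.0 ** (scenario.ec50_log10_sd * rng.standard_normal())
            out.append((spec.mutant_id, float(x), float(obs)))
            truth["ec50_true"][f"{series}:{spec.mutant_id}"] = ec50
        return out

    methyl = one_series(triad_specs(), "methyl")
    hydration = one_series(hydration_specs(), "hydration")
    return TriadPanel(methyl_series=methyl, hydration_series=hydration, truth=truth)
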