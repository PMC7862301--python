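"""Physical constants and residue annotation tables.

All energies are in kcal/mol, temperatures in K, concentrations in µM
(mM for permeant-ion concentrations in the permeation model), voltages
accepted in mV and converted to V inside the permeation math.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Gas constant, kcal mol^-1 K^-1
R_KCAL = 1.987e-3
#: Faraday constant, kcal mol^-1 V^-1 (used wherever zFV enters an exponent)
F_KCAL_PER_V = 23.061
#: Recording temperature: 20 °C
T_DEFAULT = 293.15


@dataclass(frozen=True)
class Constants:
    """Thermodynamic constants of the analysis.

    ``z`` is the valence of the permeant ion; the channel conducts
    chloride, so the default is −1.
    """

    R: float = R_KCAL
    T: float = T_DEFAULT
    F: float = F_KCAL_PER_V
    z: float = -1.0

    def __post_init__(self) -> None:
        if self.R <= 0 or self.T <= 0 or self.F <= 0:
            raise ValueError("R, T and F must be positive")

    @property
    def RT(self) -> float:
        """Thermal energy R·T in kcal/mol (0.5825 at 20 °C)."""
        return self.R * self.T


DEFAULT_CONSTANTS = Constants()

#: Gate positions on the pore-lining helices; wild type is Ile at all three.
GATE_POSITIONS = (550, 551, 641)
WT_RESIDUE = "I"

#: Kyte–Doolittle hydropathy indices for the 20 standard residues.
#: Ile is the scale maximum (4.5), consistent with its role in the
#: hydrophobic gate.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Side-chain methyl/methylene count used for hydrophobic-volume titration.
#: Only the residues whose counts the mutagenesis logic fixes are seeded
#: (Ile→Val removes one group, Ile→Ala removes three); other substitutions
#: require an explicit user entry rather than a guessed count.
METHYL_COUNTS = {"I": 3, "V": 2, "A": 0}


@dataclass
class HydropathyTable:
    """Residue → hydropathy index mapping.

    ``hydration_energy`` maps the index to a hydration free energy on the
    kcal/mol scale.  The sign convention is ΔG_hydration = −index by
    default, so hydrophilic residues carry larger (more positive)
    hydration energies and a positive hydration fraction δ left-shifts the
    EC50 of hydrophilic substitutions; set ``invert_sign=True`` to flip it.
    """

    values: dict[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    invert_sign: bool = False

    def __post_init__(self) -> None:
        missing = set(KYTE_DOOLITTLE) - set(self.values)
        if missing:
            raise ValueError(f"hydropathy table missing residues: {sorted(missing)}")

    def hydropathy(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise KeyError(f"residue {residue!r} absent from hydropathy table") from None

    def hydration_energy(self, residue: str) -> float:
        sign = 1.0 if self.invert_sign else -1.0
        return sign * self.hydropathy(residue)


DEFAULT_HYDROPATHY = HydropathyTable()
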