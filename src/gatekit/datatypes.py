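"""Domain containers for dose-response curves, I-V relations and mutants."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import GATE_POSITIONS, METHYL_COUNTS, WT_RESIDUE, HydropathyTable

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

IV_CONDITIONS = ("zero_ca", "saturating_ca", "predicted_single_occupancy")


class ValidationError(ValueError):
    """Input violates a structural contract (schema, vocabulary, ordering)."""


@dataclass(frozen=True)
class DoseResponsePoint:
    """One averaged concentration-response point: mean ± SEM over patches."""

    ca: float  # free Ca2+, µM
    response: float  # normalized current I/Imax
    sem: float = 0.0
    n_patches: int = 1

    def __post_init__(self) -> None:
        if self.ca < 0:
            raise ValidationError(f"ca must be >= 0, got {self.ca}")
        if self.sem < 0:
            raise ValidationError(f"sem must be >= 0, got {self.sem}")
        if self.n_patches < 1:
            raise ValidationError(f"n_patches must be >= 1, got {self.n_patches}")


@dataclass
class DoseResponseCurve:
    """Normalized concentration-response relation of one construct.

    Points are kept sorted by concentration; a point at ca = 0 records
    basal (ligand-independent) activity.
    """

    mutant_id: str
    points: list[DoseResponsePoint]

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda p: p.ca)
        if len(self.points) < 4:
            raise ValidationError(
                f"curve {self.mutant_id!r} needs >= 4 points, got {len(self.points)}"
            )
        ca = [p.ca for p in self.points]
        if any(a >= b for a, b in zip(ca, ca[1:])):
            raise ValidationError(
                f"curve {self.mutant_id!r} has duplicate ca values"
            )

    @property
    def ca(self) -> np.ndarray:
        return np.array([p.ca for p in self.points])

    @property
    def response(self) -> np.ndarray:
        return np.array([p.response for p in self.points])

    @property
    def sem(self) -> np.ndarray:
        return np.array([p.sem for p in self.points])

    @property
    def basal(self) -> float | None:
        """Response at zero Ca2+ if measured, else None."""
        return self.points[0].response if self.points[0].ca == 0 else None

    def nonzero(self) -> "DoseResponseCurve":
        """Copy without the ca = 0 point (used by Hill fitting).

        Built without re-validation: dropping the basal point may leave
        three points, which is still enough for a two-parameter fit.
        """
        out = object.__new__(DoseResponseCurve)
        out.mutant_id = self.mutant_id
        out.points = [p for p in self.points if p.ca > 0]
        return out


@dataclass
class IVCurve:
    """Instantaneous current-voltage relation at a stated Ca2+ condition.

    Sign convention: positive current is outward (Cl⁻ influx), so an
    outwardly rectifying pore carries |I(+80 mV)| > |I(−80 mV)|.
    """

    mutant_id: str
    condition: str
    voltages: np.ndarray  # mV
    currents: np.ndarray  # pA or normalized

    def __post_init__(self) -> None:
        if self.condition not in IV_CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; expected one of {IV_CONDITIONS}"
            )
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.voltages.shape != self.currents.shape:
            raise ValidationError("voltages and currents must have equal length")
        if np.any(np.diff(self.voltages) <= 0):
            order = np.argsort(self.voltages)
            self.voltages = self.voltages[order]
            self.currents = self.currents[order]
            if np.any(np.diff(self.voltages) <= 0):
                raise ValidationError(
                    f"curve {self.mutant_id!r}/{self.condition}: duplicate voltages"
                )

    def current_at(self, v_mv: float) -> float:
        """Linear interpolation of the current at ``v_mv``."""
        if not (self.voltages[0] <= v_mv <= self.voltages[-1]):
            raise ValidationError(
                f"{v_mv} mV outside measured range "
                f"[{self.voltages[0]}, {self.voltages[-1]}]"
            )
        return float(np.interp(v_mv, self.voltages, self.currents))


@dataclass(frozen=True)
class MutantSpec:
    """Residue identities at the three gate positions (550, 551, 641)."""

    residues: tuple[str, str, str] = (WT_RESIDUE,) * 3
    background: str = "WT"

    def __post_init__(self) -> None:
        if len(self.residues) != len(GATE_POSITIONS):
            raise ValidationError("residues must cover the three gate positions")
        for aa in self.residues:
            if aa not in VALID_AA:
                raise ValidationError(f"invalid amino-acid code {aa!r}")

    @property
    def is_wt(self) -> bool:
        return all(aa == WT_RESIDUE for aa in self.residues)

    @property
    def mutant_id(self) -> str:
        if self.is_wt:
            return "WT"
        parts = [
            f"{WT_RESIDUE}{pos}{aa}"
            for pos, aa in zip(GATE_POSITIONS, self.residues)
            if aa != WT_RESIDUE
        ]
        return "/".join(parts)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "MutantSpec":
        try:
            residues = tuple(str(mapping[str(p)]) for p in GATE_POSITIONS)
        except KeyError as exc:
            raise ValidationError(f"mutant mapping missing position {exc}") from None
        return cls(residues=residues)

    def to_mapping(self) -> dict:
        return {str(p): aa for p, aa in zip(GATE_POSITIONS, self.residues)}


@dataclass(frozen=True)
class ChemicalPerturbation:
    """A construct's chemistry change relative to wild type.

    delta_n_me: change in side-chain methyl(ene) count summed over the
        three gate positions (≤ 0 for truncations).
    ddg_hydration: change in hydration free energy (kcal/mol) under the
        configured sign convention.
    dg_mut: fitted mutant-specific gating energy (kcal/mol), if estimated.
    """

    mutant_id: str
    delta_n_me: int = 0
    ddg_hydration: float = 0.0
    dg_mut: float | None = None


def annotate_mutant(
    spec: MutantSpec,
    table: HydropathyTable | None = None,
    methyl_counts: dict[str, int] | None = None,
    require_methyl: bool = True,
) -> ChemicalPerturbation:
    """Sum the per-position methyl and hydration changes of a mutant.

    Additive over positions: the annotation of a double mutant is the sum
    of the two singles. Residues absent from the methyl table raise a
    lookup error rather than guessing a count; pass
    ``require_methyl=False`` for polarity-series constructs analysed via
    the hydration route only, whose methyl change is then reported as 0.
    """
    table = table if table is not None else HydropathyTable()
    counts = methyl_counts if methyl_counts is not None else METHYL_COUNTS
    dn = 0
    ddg = 0.0
    hyd_wt = table.hydration_energy(WT_RESIDUE)
    for aa in spec.residues:
        if aa in counts:
            dn += counts[aa] - counts[WT_RESIDUE]
        elif require_methyl:
            raise KeyError(
                f"residue {aa!r} has no methyl-count entry; add one explicitly"
            )
        ddg += table.hydration_energy(aa) - hyd_wt
    return ChemicalPerturbation(spec.mutant_id, delta_n_me=dn, ddg_hydration=ddg)


@dataclass(frozen=True)
class Measurement:
    """A value with a standard error, the currency of error propagation."""

    value: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if self.se < 0 or not math.isfinite(self.se):
            raise ValidationError(f"standard error must be finite and >= 0, got {self.se}")

    def __iter__(self):
        return iter((self.value, self.se))
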