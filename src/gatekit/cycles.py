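"""Thermodynamic mutant-cycle analysis with propagated uncertainties.

Free energies of the gating transition, ΔG = −RT ln L, are compared
across single, double and triple mutants.  Non-additivity in a
double-mutant cycle defines the coupling energy

    ΔΔΔG^XY = (ΔG^(0,0) − ΔG^(X,0)) − (ΔG^(0,Y) − ΔG^(X,Y)),

and its change upon mutating a third residue Z is the triadic coupling
ΔΔΔΔG^XYZ = ΔΔΔG^XY_{Z→0} − ΔΔΔG^XY.  Standard errors propagate in
quadrature for sums/differences and in relative quadrature for
products/quotients; deviation from zero is assessed with a two-sided
one-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import Constants, DEFAULT_CONSTANTS
from .datatypes import Measurement, ValidationError


def delta_g(
    l: float, constants: Constants = DEFAULT_CONSTANTS, se: float = 0.0
) -> Measurement:
    """ΔG = −RT ln L in kcal/mol; an SE on L propagates as RT·σ_L/L."""
    if l <= 0:
        raise ValueError(f"equilibrium constant must be positive, got {l}")
    rt = constants.RT
    return Measurement(-rt * np.log(l), rt * se / l)


def propagate_error(a: Measurement, b: Measurement, op: str) -> Measurement:
    """First-order error propagation for the four elementary operations.

    sum/difference: σ = √(σ_a² + σ_b²);
    product/quotient: σ/|f| = √((σ_a/|a|)² + (σ_b/|b|)²).
    """
    if op == "sum":
        return Measurement(a.value + b.value, float(np.hypot(a.se, b.se)))
    if op == "difference":
        return Measurement(a.value - b.value, float(np.hypot(a.se, b.se)))
    if op in ("product", "quotient"):
        if a.value == 0 or b.value == 0:
            raise ValueError(f"{op} propagation requires nonzero operands")
        f = a.value * b.value if op == "product" else a.value / b.value
        rel = np.hypot(a.se / abs(a.value), b.se / abs(b.value))
        return Measurement(f, float(abs(f) * rel))
    raise ValueError(f"unknown operation {op!r}")


def ddg(dg_a: Measurement, dg_b: Measurement) -> Measurement:
    """ΔΔG = ΔG_a − ΔG_b with quadrature SE."""
    return propagate_error(dg_a, dg_b, "difference")


@dataclass(frozen=True)
class Cycle:
    """The four corners of a double-mutant cycle.

    ``g_wt`` has both residues intact, ``g_x``/``g_y`` carry the single
    mutations, ``g_xy`` the double mutation.
    """

    g_wt: Measurement
    g_x: Measurement
    g_y: Measurement
    g_xy: Measurement

    @classmethod
    def from_corners(cls, corners: dict[str, Measurement]) -> "Cycle":
        missing = [k for k in ("wt", "x", "y", "xy") if k not in corners]
        if missing:
            raise ValidationError(f"cycle missing corner(s): {missing}")
        return cls(corners["wt"], corners["x"], corners["y"], corners["xy"])


def coupling_energy(cycle: Cycle) -> Measurement:
    """ΔΔΔG of a double-mutant cycle; zero for additive mutations.

    Computed along the X path and asserted identical along the Y path
    (an algebraic identity, so any difference is a programming error).
    """
    via_x = ddg(ddg(cycle.g_xy, cycle.g_y), ddg(cycle.g_x, cycle.g_wt))
    via_y = ddg(ddg(cycle.g_xy, cycle.g_x), ddg(cycle.g_y, cycle.g_wt))
    assert abs(via_x.value - via_y.value) < 1e-12 * max(1.0, abs(via_x.value)), (
        "path dependence in cycle algebra"
    )
    return via_x


def triple_coupling(
    cycle_base: Measurement, cycle_z_mutated: Measurement
) -> Measurement:
    """ΔΔΔΔG^XYZ = ΔΔΔG^XY_{Z→0} − ΔΔΔG^XY with quadrature SE."""
    return ddg(cycle_z_mutated, cycle_base)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    significant: bool
    dof: int


def one_sample_t(value: float, se: float, dof: int, alpha: float = 0.05) -> TTestResult:
    """Two-sided one-sample t-test of deviation from zero (t = value/SE)."""
    if dof < 1:
        raise ValueError(f"dof must be >= 1, got {dof}")
    if se < 0:
        raise ValueError("se must be >= 0")
    if se == 0:
        warnings.warn("zero standard error: degenerate t-test", stacklevel=2)
        p = 1.0 if value == 0 else 0.0
        t = 0.0 if value == 0 else np.inf * np.sign(value)
        return TTestResult(float(t), p, p < alpha, dof)
    t = value / se
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return TTestResult(float(t), p, p < alpha, dof)


@dataclass
class CycleEnergies:
    """Full coupling report for one residue pair (and optional third residue)."""

    pair: tuple[str, str]
    coupling: Measurement
    test: TTestResult
    background: str = "WT"

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "background": self.background,
            "coupling_kcal_mol": self.coupling.value,
            "se": self.coupling.se,
            "t": self.test.t,
            "p": self.test.p,
            "significant": self.test.significant,
            "dof": self.test.dof,
        }


def analyze_pair(
    pair: tuple[str, str],
    corners: dict[str, Measurement],
    dof: int,
    background: str = "WT",
) -> CycleEnergies:
    """Coupling energy and significance test for one double-mutant cycle."""
    cycle = Cycle.from_corners(corners)
    coupling = coupling_energy(cycle)
    test = one_sample_t(coupling.value, coupling.se, dof)
    return CycleEnergies(pair=pair, coupling=coupling, test=test, background=background)
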