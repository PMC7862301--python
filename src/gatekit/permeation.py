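"""Minimal n-barrier model of ion permeation and I-V fitting.

The open pore is modelled as n sequential Eyring barriers.  With σ_h and
σ_β the crossing rates at the middle and innermost barriers relative to
the outermost one, the instantaneous current is

    I = zFA e^{zFV/2nRT} (c_i − c_o e^{−zFV/RT}) /
        (e^{−zFV(n−1)/nRT} + (1/σ_h)(1 − e^{−zFV(n−2)/nRT})/(e^{zFV/nRT} − 1) + 1/σ_β)

A = β₀ν sets the current scale.  Unequal barrier heights produce
rectification: a small σ_β (high innermost barrier) yields the outwardly
rectifying phenotype of basally active gate mutants.  Relative rates map
to activation-energy differences via ΔE_a(σ) = −RT ln σ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .constants import Constants, DEFAULT_CONSTANTS
from .datatypes import IVCurve, ValidationError
from .fitting import FitResult, least_squares_fit


@dataclass(frozen=True)
class PermeationParams:
    """Parameters of the n-barrier permeation model.

    c_i and c_o are intra-/extracellular permeant concentrations in mM;
    the defaults reflect symmetrical 150 mM Cl⁻ recording solutions.
    """

    A: float
    sigma_h: float
    sigma_beta: float
    n: int = 3
    c_i: float = 150.0
    c_o: float = 150.0
    constants: Constants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if self.A <= 0 or self.sigma_h <= 0 or self.sigma_beta <= 0:
            raise ValueError("A, sigma_h and sigma_beta must be positive")
        if self.n < 3:
            raise ValueError(f"need n >= 3 barriers, got {self.n}")
        if self.c_i <= 0 or self.c_o <= 0:
            raise ValueError("concentrations must be positive")

    def fixed_compatible(self, other: "PermeationParams") -> bool:
        return (
            self.n == other.n
            and self.c_i == other.c_i
            and self.c_o == other.c_o
            and self.constants == other.constants
        )


@dataclass(frozen=True)
class BarrierEnergies:
    """Activation energies of the innermost and middle barriers relative
    to the outermost one, kcal/mol."""

    dEa_sigma_beta: float
    dEa_sigma_h: float


def barrier_current(v_mv, params: PermeationParams):
    """Current at membrane potential ``v_mv`` (mV, scalar or array).

    The middle-barrier term has a removable singularity at V = 0 that is
    evaluated by its analytic limit (→ n − 2); elsewhere expm1 keeps the
    ratio accurate for small voltages.
    """
    v = np.asarray(v_mv, dtype=float) * 1e-3  # mV -> V
    if np.any(~np.isfinite(v)):
        raise ValueError("voltage must be finite")
    c = params.constants
    n = params.n
    a = c.z * c.F * v / (n * c.R * c.T)  # zFV/nRT, dimensionless

    numerator = params.c_i - params.c_o * np.exp(-n * a)
    with np.errstate(invalid="ignore", divide="ignore"):
        middle = np.where(
            a == 0.0,
            float(n - 2),
            -np.expm1(-(n - 2) * np.where(a == 0.0, 1.0, a))
            / np.expm1(np.where(a == 0.0, 1.0, a)),
        )
    denom = np.exp(-(n - 1) * a) + middle / params.sigma_h + 1.0 / params.sigma_beta
    current = c.z * c.F * params.A * np.exp(a / 2.0) * numerator / denom
    if np.any(~np.isfinite(current)):
        raise FloatingPointError("permeation current evaluated to NaN/inf")
    return current if current.ndim else float(current)


def nernst_potential(params: PermeationParams) -> float:
    """Reversal potential (RT/zF)·ln(c_o/c_i) in mV."""
    c = params.constants
    return 1e3 * c.R * c.T / (c.z * c.F) * np.log(params.c_o / params.c_i)


def curve_from_params(
    params: PermeationParams,
    voltages_mv,
    mutant_id: str = "model",
    condition: str = "saturating_ca",
) -> IVCurve:
    """Evaluate the model on a voltage grid and wrap it as an IVCurve."""
    v = np.asarray(voltages_mv, dtype=float)
    return IVCurve(mutant_id, condition, v, barrier_current(v, params))


def fit_iv(
    curve: IVCurve,
    n: int = 3,
    c_i: float = 150.0,
    c_o: float = 150.0,
    constants: Constants = DEFAULT_CONSTANTS,
) -> tuple[PermeationParams, FitResult]:
    """Fit (A, σ_h, σ_β) to an instantaneous I-V relation.

    All three parameters are fitted as natural logs, which enforces
    positivity without constrained optimization; the logs are kept within
    ±15 (a ~3 × 10⁶-fold range around the scale guess) so that a rate the
    data cannot pin down — a barrier far from rate-limiting — lands on the
    bound with a correspondingly enormous confidence interval instead of
    drifting to infinity.  Four deterministic starting points spanning
    weak to strong rectification are tried and the best SSR kept.
    """
    v = curve.voltages
    y = curve.currents
    if len(v) < 5:
        raise ValidationError("need >= 5 voltage points")
    if v[0] >= 0 or v[-1] <= 0:
        warnings.warn(
            "I-V data cover a single polarity; the fit may be ill-conditioned",
            stacklevel=2,
        )

    def make(x):
        return PermeationParams(
            A=np.exp(x[0]), sigma_h=np.exp(x[1]), sigma_beta=np.exp(x[2]),
            n=n, c_i=c_i, c_o=c_o, constants=constants,
        )

    def residuals(x):
        return barrier_current(v, make(x)) - y

    # scale guess: match the largest-|I| point with sigma = 1
    ref = PermeationParams(1.0, 1.0, 1.0, n=n, c_i=c_i, c_o=c_o, constants=constants)
    model_ref = barrier_current(v, ref)
    k = int(np.argmax(np.abs(y)))
    a0 = abs(y[k] / model_ref[k]) if model_ref[k] != 0 else 1.0
    a0 = max(a0, 1e-12)

    lo = np.log(a0) - 15.0, -15.0, -15.0
    hi = np.log(a0) + 15.0, 15.0, 15.0
    best = None
    for s_h0, s_b0 in [(1.0, 1.0), (0.5, 0.05), (1.0, 0.01), (0.1, 1.0)]:
        x0 = np.log([a0, s_h0, s_b0])
        try:
            fit = least_squares_fit(
                residuals, x0,
                names=["A", "sigma_h", "sigma_beta"],
                n_data=len(y),
                log_mask=[True, True, True],
                bounds=(lo, hi),
            )
        except Exception:
            continue
        if best is None or fit.ssr < best.ssr:
            best = fit
    if best is None:
        raise RuntimeError("I-V fit failed from every starting point")
    params = make(np.log([best.param("A"), best.param("sigma_h"), best.param("sigma_beta")]))
    return params, best


def barrier_energies(
    sigma_h: float, sigma_beta: float, constants: Constants = DEFAULT_CONSTANTS
) -> BarrierEnergies:
    """ΔE_a(σ) = −RT ln σ for the middle and innermost barriers."""
    if sigma_h <= 0 or sigma_beta <= 0:
        raise ValueError("relative rates must be positive")
    rt = constants.RT
    return BarrierEnergies(
        dEa_sigma_beta=-rt * np.log(sigma_beta),
        dEa_sigma_h=-rt * np.log(sigma_h),
    )


def predict_single_occupancy_iv(
    fit_zero: PermeationParams,
    fit_sat: PermeationParams,
    voltages_mv,
    mutant_id: str = "model",
    scale_mode: str = "log_interp",
) -> tuple[IVCurve, PermeationParams]:
    """Predicted I-V curve at single Ca²⁺ occupancy.

    Barrier energies of the apo (zero Ca²⁺) and doubly occupied
    (saturating) fits are linearly interpolated at their midpoint and
    mapped back to rates via σ = e^{−ΔE/RT}.  The scale A is interpolated
    on a log scale by default (``scale_mode='log_interp'``); pass
    ``'saturating'`` to reuse the saturating-condition scale instead.
    """
    if not fit_zero.fixed_compatible(fit_sat):
        raise ValidationError("apo and saturating fits differ in fixed parameters")
    rt = fit_zero.constants.RT
    e_zero = barrier_energies(fit_zero.sigma_h, fit_zero.sigma_beta, fit_zero.constants)
    e_sat = barrier_energies(fit_sat.sigma_h, fit_sat.sigma_beta, fit_sat.constants)
    e_h = 0.5 * (e_zero.dEa_sigma_h + e_sat.dEa_sigma_h)
    e_b = 0.5 * (e_zero.dEa_sigma_beta + e_sat.dEa_sigma_beta)
    if scale_mode == "log_interp":
        a_single = float(np.exp(0.5 * (np.log(fit_zero.A) + np.log(fit_sat.A))))
    elif scale_mode == "saturating":
        a_single = fit_sat.A
    else:
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    params = replace(
        fit_sat,
        A=a_single,
        sigma_h=float(np.exp(-e_h / rt)),
        sigma_beta=float(np.exp(-e_b / rt)),
    )
    curve = curve_from_params(
        params, voltages_mv, mutant_id=mutant_id, condition="predicted_single_occupancy"
    )
    return curve, params
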