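"""Six-state MWC activation model with occupancy-dependent conductances.

A closed and an open state are connected by two identical Ca²⁺-binding
steps (scheme C0..C2 / O0..O2).  With x the free Ca²⁺ concentration, the
binding polynomials are the printed trinomials of sequential binding with
equal macroscopic constants,

    Q_C = 1 + x/K_d(C) + (x/K_d(C))²,   Q_O likewise,

the open-state occupancies are P_Oi = L₀ (x/K_d(O))^i / (Q_C + L₀ Q_O),
and microscopic reversibility fixes L₀ = L₂ (K_d(O)/K_d(C))².  The open
channel carries relative current levels (i, j, k) at occupancy (0, 1, 2),
with k normalized to 1, so the normalized response is

    I/Imax = (i P_O0 + j P_O1 + k P_O2) / (k L₂/(1+L₂)).

Chemical perturbations of the gate enter exclusively through the gating
constant: L₂ scales exponentially with the number of removed methyl
groups (per-methyl energy ΔG_Me), with a fraction δ of the residues'
hydration-energy change, or with a mutant-specific gating energy ΔG_mut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .constants import Constants, DEFAULT_CONSTANTS
from .datatypes import DoseResponseCurve, ValidationError
from .fitting import DegenerateDataError, FitResult, least_squares_fit


class FlatResponseError(ValueError):
    """The model curve has no half-maximum crossing (no EC50)."""


def l0_from_reversibility(l2: float, kd_o: float, kd_c: float) -> float:
    """L₀ = L₂ (K_d(O))² / (K_d(C))², the microscopic-reversibility identity."""
    if l2 <= 0 or kd_o <= 0 or kd_c <= 0:
        raise ValueError("l2, kd_o and kd_c must be positive")
    return l2 * (kd_o / kd_c) ** 2


@dataclass(frozen=True)
class MWCParams:
    """Binding and gating constants of the six-state model.

    kd_c, kd_o: closed-/open-state dissociation constants (µM).
    l2: closed→open equilibrium constant at double occupancy.
    l0 is always the derived reversibility value, never set independently.
    """

    kd_c: float
    kd_o: float
    l2: float

    def __post_init__(self) -> None:
        if self.kd_c <= 0 or self.kd_o <= 0 or self.l2 <= 0:
            raise ValueError("kd_c, kd_o and l2 must be positive")

    @property
    def l0(self) -> float:
        return l0_from_reversibility(self.l2, self.kd_o, self.kd_c)

    @property
    def p_o_inf(self) -> float:
        """Limiting open probability L₂/(1+L₂) at saturating Ca²⁺."""
        return self.l2 / (1.0 + self.l2)


@dataclass(frozen=True)
class ConductanceLevels:
    """Relative current levels at Ca²⁺ occupancy 0 and 1; k ≡ 1."""

    i_over_k: float = 0.0
    j_over_k: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.i_over_k <= 1.0 and 0.0 <= self.j_over_k <= 1.0):
            warnings.warn(
                f"conductance levels outside [0, 1]: i/k={self.i_over_k}, "
                f"j/k={self.j_over_k}",
                stacklevel=2,
            )
        elif self.i_over_k > self.j_over_k:
            warnings.warn(
                "expected ordering i/k <= j/k violated", stacklevel=2
            )


DEFAULT_LEVELS = ConductanceLevels(0.0, 0.0)


@dataclass(frozen=True)
class StateOccupancies:
    p_c0: float
    p_c1: float
    p_c2: float
    p_o0: float
    p_o1: float
    p_o2: float
    p_o_inf: float
    q_c: float
    q_o: float

    @property
    def total(self) -> float:
        return self.p_c0 + self.p_c1 + self.p_c2 + self.p_o0 + self.p_o1 + self.p_o2


def state_occupancies(ca: float, params: MWCParams) -> StateOccupancies:
    """Equilibrium occupancy of the six states at free Ca²⁺ ``ca`` (µM)."""
    if ca < 0:
        raise ValueError("ca must be >= 0")
    xc = ca / params.kd_c
    xo = ca / params.kd_o
    q_c = 1.0 + xc + xc**2
    q_o = 1.0 + xo + xo**2
    l0 = params.l0
    denom = q_c + l0 * q_o
    return StateOccupancies(
        p_c0=1.0 / denom,
        p_c1=xc / denom,
        p_c2=xc**2 / denom,
        p_o0=l0 / denom,
        p_o1=l0 * xo / denom,
        p_o2=l0 * xo**2 / denom,
        p_o_inf=params.p_o_inf,
        q_c=q_c,
        q_o=q_o,
    )


def normalized_response(ca, params: MWCParams, levels: ConductanceLevels = DEFAULT_LEVELS):
    """Normalized current I/Imax at ``ca`` (µM, scalar or array).

    Tends to 1 as ca → ∞ by construction of the normalization.
    """
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("ca must be >= 0")
    xc = ca / params.kd_c
    xo = ca / params.kd_o
    q_c = 1.0 + xc + xc**2
    q_o = 1.0 + xo + xo**2
    l0 = params.l0
    denom = q_c + l0 * q_o
    num = l0 * (levels.i_over_k + levels.j_over_k * xo + xo**2)
    out = num / denom / params.p_o_inf
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# chemical parameterizations of the gating constant

def l2_from_methyl(
    delta_n_me: float, dg_me: float, l2_wt: float,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """L₂(Δn_Me) = L₂WT e^{−Δn_Me ΔG_Me/RT}: removing methyl groups
    (Δn_Me < 0, ΔG_Me > 0) destabilizes the closed state."""
    if l2_wt <= 0:
        raise ValueError("l2_wt must be positive")
    return l2_wt * np.exp(-delta_n_me * dg_me / constants.RT)


def l2_from_hydration(
    ddg_hydration: float, delta: float, l2_wt: float,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """L₂(ΔΔG_hydration) = L₂WT e^{δ ΔΔG_hydration/RT}: a fraction δ of a
    residue's hydration-energy change contributes to the gating step."""
    if l2_wt <= 0:
        raise ValueError("l2_wt must be positive")
    return l2_wt * np.exp(delta * ddg_hydration / constants.RT)


def l2_from_mutant(
    dg_mut: float, l2_wt: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """L₂mut = L₂WT e^{−ΔG_mut/RT} (ΔG_mut < 0 stabilizes the open state)."""
    if l2_wt <= 0:
        raise ValueError("l2_wt must be positive")
    return l2_wt * np.exp(-dg_mut / constants.RT)


# ---------------------------------------------------------------------------
# model EC50

_LOG10_CA_RANGE = (-4.0, 4.0)  # µM


def _response_at_log10(log10_ca, params, levels):
    return normalized_response(10.0**np.asarray(log10_ca, dtype=float), params, levels)


def model_ec50(
    params: MWCParams,
    levels: ConductanceLevels = DEFAULT_LEVELS,
    rel_tol: float = 1e-6,
) -> float:
    """Concentration (µM) where the response crosses halfway between its
    basal value response(0) and the saturating value 1.

    Found by bracketing root search on log₁₀-concentration over
    [10⁻⁴, 10⁴] µM; a parameterization with no dynamic range (e.g.
    kd_o = kd_c with uniform conductance levels) has no EC50.
    """
    r0 = float(normalized_response(0.0, params, levels))
    half = 0.5 * (r0 + 1.0)
    lo, hi = _LOG10_CA_RANGE
    r_hi = float(_response_at_log10(hi, params, levels))
    if abs(r_hi - r0) < 1e-9:
        raise FlatResponseError(
            "response has no dynamic range; EC50 undefined"
        )
    f = lambda lx: float(_response_at_log10(lx, params, levels)) - half
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise FlatResponseError(
            "half-maximum not bracketed in [1e-4, 1e4] µM"
        )
    root = optimize.brentq(f, lo, hi, xtol=rel_tol, rtol=8.9e-16)
    return float(10.0**root)


def _model_ec50_vec(
    kd_c, kd_o, l2, i_over_k, j_over_k, n_iter: int = 60
) -> np.ndarray:
    """Vectorized bisection for the EC50 of many parameterizations at once.

    Same half-crossing definition as :func:`model_ec50`; used inside the
    global chemical fit where EC50s of a whole mutant panel are needed per
    objective evaluation.
    """
    kd_c = np.asarray(kd_c, float)
    kd_o = np.asarray(kd_o, float)
    l2 = np.asarray(l2, float)
    i_over_k = np.asarray(i_over_k, float)
    j_over_k = np.asarray(j_over_k, float)

    def resp(ca):
        xc = ca / kd_c
        xo = ca / kd_o
        l0 = l2 * (kd_o / kd_c) ** 2
        num = l0 * (i_over_k + j_over_k * xo + xo**2)
        denom = 1.0 + xc + xc**2 + l0 * (1.0 + xo + xo**2)
        return num / denom / (l2 / (1.0 + l2))

    r0 = resp(np.zeros_like(kd_c + 0.0 * l2))
    half = 0.5 * (r0 + 1.0)
    lo = np.full(np.broadcast_shapes(kd_c.shape, l2.shape), _LOG10_CA_RANGE[0])
    hi = np.full_like(lo, _LOG10_CA_RANGE[1])
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        below = resp(10.0**mid) < half
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 10.0 ** (0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# sub-conductance levels from I-V analysis

def subconductance_ratios(
    iv_zero, iv_sat, iv_single, v_mv: float = 80.0
) -> ConductanceLevels:
    """i/k and j/k from fitted/predicted I-V relations at +80 mV.

    i/k = I_zero/I_sat and j/k = I_single/I_sat; values are clipped to
    [0, 1] with a warning when measurement scatter pushes them outside.
    """
    i_sat = iv_sat.current_at(v_mv)
    if i_sat <= 0:
        raise DegenerateDataError(
            f"saturating current at +{v_mv} mV must be positive, got {i_sat}"
        )
    i_zero = iv_zero.current_at(v_mv)
    i_single = iv_single.current_at(v_mv)
    i_over_k = i_zero / i_sat
    j_over_k = i_single / i_sat
    clipped_i = min(max(i_over_k, 0.0), 1.0)
    clipped_j = min(max(j_over_k, 0.0), 1.0)
    if (clipped_i, clipped_j) != (i_over_k, j_over_k):
        warnings.warn(
            f"sub-conductance ratios clipped to [0, 1]: i/k={i_over_k:.3g}, "
            f"j/k={j_over_k:.3g}",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ConductanceLevels(clipped_i, clipped_j)


# ---------------------------------------------------------------------------
# global chemical fit (methyl + hydration series, shared binding constants)

@dataclass
class ChemicalFit:
    """Result of the global two-series fit.

    dg_me: effective per-methyl-group energy stabilizing the closed state
        (kcal/mol).
    delta: fraction of the hydration-energy change contributing to gating.
    kd_c, kd_o: binding constants (µM) shared across both series.
    """

    dg_me: float
    delta: float
    kd_c: float
    kd_o: float
    fit: FitResult


def fit_chemical_global(
    methyl_series: list[tuple[float, float]],
    hydration_series: list[tuple[float, float]],
    l2_wt: float,
    levels: ConductanceLevels = DEFAULT_LEVELS,
    levels_methyl: list[ConductanceLevels] | None = None,
    levels_hydration: list[ConductanceLevels] | None = None,
    constants: Constants = DEFAULT_CONSTANTS,
    n_starts: int = 8,
    seed: int = 2021,
) -> ChemicalFit:
    """Globally fit {K_d(C), K_d(O), ΔG_Me, δ} to two EC50 series.

    ``methyl_series`` holds (Δn_Me, EC50_exp) pairs of the
    hydrophobic-volume titration and ``hydration_series`` (ΔΔG_hydration,
    EC50_exp) pairs of the polarity titration.  The objective is the sum
    of squared differences between log₁₀ model and experimental EC50s over
    both series jointly, with the binding constants shared; L₂WT is a
    fixed input.  ``levels`` applies to every construct unless per-entry
    levels (same order as the series) are given for mutants with measured
    basal conduction.  The optimizer is restarted from ``n_starts``
    log-spaced initial binding constants (seeded) and the best SSR kept.
    """
    if len(methyl_series) < 3 or len(hydration_series) < 3:
        raise DegenerateDataError("need >= 3 mutants per series (including WT)")
    if l2_wt <= 0:
        raise ValueError("l2_wt must be positive")
    dn = np.array([m[0] for m in methyl_series], float)
    ec_me = np.array([m[1] for m in methyl_series], float)
    ddg = np.array([h[0] for h in hydration_series], float)
    ec_hy = np.array([h[1] for h in hydration_series], float)
    if np.any(ec_me <= 0) or np.any(ec_hy <= 0):
        raise ValueError("experimental EC50s must be positive")
    log_ec_obs = np.log10(np.concatenate([ec_me, ec_hy]))
    rt = constants.RT

    lev_me = levels_methyl if levels_methyl is not None else [levels] * len(dn)
    lev_hy = levels_hydration if levels_hydration is not None else [levels] * len(ddg)
    if len(lev_me) != len(dn) or len(lev_hy) != len(ddg):
        raise ValueError("per-entry levels must match the series lengths")
    i_over_k = np.array([l.i_over_k for l in lev_me] + [l.i_over_k for l in lev_hy])
    j_over_k = np.array([l.j_over_k for l in lev_me] + [l.j_over_k for l in lev_hy])

    def residuals(x):
        kd_c, kd_o = np.exp(x[0]), np.exp(x[1])
        dg_me, delta = x[2], x[3]
        l2 = np.concatenate([
            l2_wt * np.exp(-dn * dg_me / rt),
            l2_wt * np.exp(delta * ddg / rt),
        ])
        ec_model = _model_ec50_vec(kd_c, kd_o, l2, i_over_k, j_over_k)
        return np.log10(ec_model) - log_ec_obs

    # data-driven start grid: binding constants bracketing the observed EC50s
    rng = np.random.default_rng(seed)
    ec_all = np.concatenate([ec_me, ec_hy])
    center = np.log(np.exp(np.mean(np.log(ec_all))))
    best = None
    for k in range(n_starts):
        ln_kd_c = center + np.log(10.0) * rng.uniform(0.0, 2.0)
        ln_kd_o = center - np.log(10.0) * rng.uniform(0.0, 2.0)
        x0 = np.array([ln_kd_c, ln_kd_o, 0.5, 0.2])
        try:
            fit = least_squares_fit(
                residuals, x0,
                names=["kd_c", "kd_o", "dg_me", "delta"],
                n_data=len(log_ec_obs),
                log_mask=[True, True, False, False],
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if best is None or fit.ssr < best.ssr:
            best = fit
    if best is None:
        raise RuntimeError("global chemical fit failed from every start")
    return ChemicalFit(
        dg_me=best.param("dg_me"),
        delta=best.param("delta"),
        kd_c=best.param("kd_c"),
        kd_o=best.param("kd_o"),
        fit=best,
    )


# ---------------------------------------------------------------------------
# per-mutant gating energy from full curves

def fit_mutant_deltaG(
    curves: list[DoseResponseCurve],
    kd_c: float,
    kd_o: float,
    l2_wt: float,
    levels_by_mutant: dict[str, ConductanceLevels] | None = None,
    constants: Constants = DEFAULT_CONSTANTS,
) -> dict[str, FitResult]:
    """One gating energy ΔG_mut per mutant, binding constants shared.

    Each mutant's full concentration-response relation is fitted (not its
    EC50 alone); because curves share no free parameters the total SSQ
    separates into per-mutant fits.  A mutant whose curve has no dynamic
    range is flagged (mapped to None) while the others proceed.
    """
    levels_by_mutant = levels_by_mutant or {}
    results: dict[str, FitResult | None] = {}
    for curve in curves:
        levels = levels_by_mutant.get(curve.mutant_id, DEFAULT_LEVELS)
        ca = curve.ca
        y = curve.response
        if np.ptp(y) < 1e-9:
            warnings.warn(
                f"mutant {curve.mutant_id!r}: flat curve, ΔG_mut not fitted",
                stacklevel=2,
            )
            results[curve.mutant_id] = None
            continue

        def residuals(x, ca=ca, y=y, levels=levels):
            params = MWCParams(kd_c, kd_o, l2_from_mutant(x[0], l2_wt, constants))
            return normalized_response(ca, params, levels) - y

        results[curve.mutant_id] = least_squares_fit(
            residuals, np.array([0.0]),
            names=["dg_mut"], n_data=len(y),
        )
    return results
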