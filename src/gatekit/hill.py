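"""Hill-equation evaluation and fitting of concentration-response data.

The normalized response is I/Imax = 1 / (1 + (EC50/[Ca²⁺])^h) with fixed
asymptotes 0 and 1.  Curves with basal activity keep their ca = 0 point
out of the fit and report the basal level separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import DoseResponseCurve
from .fitting import DegenerateDataError, FitResult, least_squares_fit


@dataclass(frozen=True)
class HillParams:
    ec50: float  # µM
    h: float  # Hill coefficient

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if self.h <= 0:
            raise ValueError(f"h must be > 0, got {self.h}")


def hill_response(ca, params: HillParams):
    """Normalized response at free Ca²⁺ ``ca`` (µM); 0 at ca = 0 (limit)."""
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("ca must be >= 0")
    out = np.zeros_like(ca)
    pos = ca > 0
    out[pos] = 1.0 / (1.0 + (params.ec50 / ca[pos]) ** params.h)
    return out if out.ndim else float(out)


def fit_hill(
    curve: DoseResponseCurve, weighted: bool = False
) -> tuple[HillParams, FitResult]:
    """Least-squares (EC50, h) fit of one averaged curve.

    Unweighted by default, matching fits of averaged relations; with
    ``weighted`` each residual is divided by the point's SEM.  EC50 is
    fitted on a log scale to guarantee positivity.
    """
    fit_curve = curve.nonzero()
    ca = fit_curve.ca
    y = fit_curve.response
    if len(np.unique(ca)) < 2:
        raise DegenerateDataError("need >= 2 distinct nonzero concentrations")
    if np.ptp(y) < 1e-12:
        raise DegenerateDataError(
            f"curve {curve.mutant_id!r}: responses are constant, Hill fit undefined"
        )
    if weighted:
        sem = fit_curve.sem
        if np.any(sem <= 0):
            raise ValueError("weighted fit requires positive SEM at every point")
        w = 1.0 / sem
    else:
        w = np.ones_like(y)

    # initial EC50: concentration of the point closest to half-max; h = 1
    ec50_0 = ca[np.argmin(np.abs(y - 0.5))]

    def residuals(x):
        p = HillParams(np.exp(x[0]), np.exp(x[1]))
        return w * (hill_response(ca, p) - y)

    fit = least_squares_fit(
        residuals,
        x0=np.array([np.log(ec50_0), 0.0]),
        names=["ec50", "h"],
        n_data=len(y),
        log_mask=[True, True],
    )
    params = HillParams(fit.param("ec50"), fit.param("h"))
    return params, fit
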