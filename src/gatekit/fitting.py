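"""Nonlinear least squares with Jacobian-based uncertainty.

Parameter variances are the diagonal of (JᵀJ)⁻¹ scaled by
SSR/(n_data − n_parameters); standard errors are their square roots and
95% confidence intervals use the Student-t quantile at n − p degrees of
freedom (slightly wider than ±1.96·SE at small n, identical in the limit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


class ConvergenceError(RuntimeError):
    """The optimizer failed to reach a minimum."""


class DegenerateDataError(ValueError):
    """The data carry no information about the parameters (e.g. flat curve)."""


class UnidentifiableParameterError(ValueError):
    """The Jacobian at the optimum is rank-deficient."""


@dataclass
class FitResult:
    """Least-squares estimate with its uncertainty report.

    ``jacobian`` is taken at the optimum in the optimizer's internal
    coordinates; ``param_scale`` holds dθ/dx of each reported parameter θ
    with respect to its internal coordinate x (θ itself for log-fitted
    parameters), so variances transfer by the delta method.
    """

    names: list[str]
    values: np.ndarray
    ssr: float
    n_data: int
    n_params: int
    jacobian: np.ndarray
    param_scale: np.ndarray | None = None
    variance: np.ndarray = field(init=False)
    se: np.ndarray = field(init=False)
    ci95: np.ndarray = field(init=False)  # shape (p, 2)

    def __post_init__(self) -> None:
        if self.n_data <= self.n_params:
            raise DegenerateDataError(
                f"need n_data > n_parameters, got {self.n_data} <= {self.n_params}"
            )
        self.values = np.asarray(self.values, dtype=float)
        self.jacobian = np.asarray(self.jacobian, dtype=float)
        self.variance, self.se, self.ci95 = confidence_intervals(
            self.jacobian, self.ssr, self.n_data, self.values,
            scale=self.param_scale,
        )

    @property
    def dof(self) -> int:
        return self.n_data - self.n_params

    def param(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def ci_of(self, name: str) -> tuple[float, float]:
        lo, hi = self.ci95[self.names.index(name)]
        return float(lo), float(hi)

    def covers(self, name: str, truth: float) -> bool:
        lo, hi = self.ci_of(name)
        return lo <= truth <= hi

    def to_dict(self) -> dict:
        return {
            "parameters": {
                n: {
                    "value": float(v),
                    "se": float(s),
                    "ci95": [float(self.ci95[i, 0]), float(self.ci95[i, 1])],
                }
                for i, (n, v, s) in enumerate(zip(self.names, self.values, self.se))
            },
            "ssr": float(self.ssr),
            "n_data": self.n_data,
            "n_parameters": self.n_params,
            "dof": self.dof,
        }


def confidence_intervals(
    jacobian: np.ndarray,
    ssr: float,
    n_data: int,
    values: np.ndarray,
    scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Variance, SE and 95% CI from the Jacobian at the optimum.

    ``scale`` (delta method) maps internal-coordinate variances to the
    reported parameter scale: var_θ = scale² · var_x.  Raises
    :class:`UnidentifiableParameterError` naming the null-space direction
    when JᵀJ is singular.
    """
    J = np.atleast_2d(np.asarray(jacobian, dtype=float))
    n_params = J.shape[1]
    dof = n_data - n_params
    if dof <= 0:
        raise DegenerateDataError("no residual degrees of freedom")
    u, s, vt = np.linalg.svd(J, full_matrices=False)
    if s[0] == 0 or s[-1] / s[0] < 1e-12:
        direction = vt[-1]
        raise UnidentifiableParameterError(
            f"rank-deficient Jacobian; null-space direction {np.round(direction, 4)}"
        )
    # diag((JtJ)^-1) via the SVD, avoids forming the inverse
    cov_diag = ((vt.T / s) ** 2).sum(axis=1) * (ssr / dof)
    if scale is not None:
        cov_diag = cov_diag * np.asarray(scale, dtype=float) ** 2
    se = np.sqrt(cov_diag)
    q = stats.t.ppf(0.975, dof)
    ci = np.column_stack([values - q * se, values + q * se])
    return cov_diag, se, ci


def least_squares_fit(
    residuals,
    x0: np.ndarray,
    names: list[str],
    n_data: int,
    log_mask: np.ndarray | None = None,
    bounds=(-np.inf, np.inf),
    **kwargs,
) -> FitResult:
    """Run scipy's trust-region least squares and build a FitResult.

    ``log_mask`` marks internal coordinates that are natural logs of the
    reported parameters: positivity is enforced without constraints, the
    rank check runs in the well-conditioned log coordinates, and SEs/CIs
    transfer to the natural scale by the delta method (SE_θ = θ·SE_lnθ).
    """
    opts = dict(method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
    opts.update(kwargs)
    sol = optimize.least_squares(residuals, x0, bounds=bounds, **opts)
    if not sol.success:
        raise ConvergenceError(
            f"least squares did not converge: {sol.message} (best SSR {sol.cost * 2:.3g})"
        )
    values = sol.x.copy()
    scale = np.ones_like(values)
    if log_mask is not None:
        log_mask = np.asarray(log_mask, dtype=bool)
        values[log_mask] = np.exp(values[log_mask])
        scale[log_mask] = values[log_mask]
    ssr = float(np.sum(sol.fun**2))
    return FitResult(
        names=list(names),
        values=values,
        ssr=ssr,
        n_data=n_data,
        n_params=len(names),
        jacobian=sol.jac.copy(),
        param_scale=scale,
    )
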