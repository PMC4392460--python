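"""Least-squares CDF fitting of the true-MTR template to observed MTRs.

The two template parameters (p0, theta) are chosen so that the model's
observed-MTR cumulative distribution (template convolved with the Gaussian
measurement error) matches the empirical CDF in the least-squares sense on
the integer lattice spanning the data padded by three error SDs.  The
measurement-error SD is *not* co-estimated: it is characterized first from
test-retest (hour-3 vs hour-4) data and passed in fixed, mirroring the
two-stage structure of the analysis.

The search is a derivative-free Nelder–Mead simplex on transformed
coordinates (logit p0, log theta), which enforces the bounds while keeping
the objective smooth.  The objective is nearly flat in theta when p0
approaches 1 (with almost no responders the responder scale is
unidentifiable), so the search restarts from three deterministically
jittered initial points and such fits are flagged ``ill_conditioned``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .hydrops_model import ErrorModel, TemplateParams, build_template, model_cdf_on_grid

__all__ = ["FitResult", "GoodnessOfFit", "fit_template", "goodness_of_fit"]

_LOG_THETA_MIN, _LOG_THETA_MAX = np.log(1e-2), np.log(200.0)
_JITTERS = ((0.0, 0.0), (0.8, -0.6), (-0.8, 0.6))


@dataclass(frozen=True)
class FitResult:
    """Fitted template parameters with diagnostics.

    ``sse`` is the sum of squared CDF differences at the integer grid
    points; ``ill_conditioned`` flags small samples (n < 20) and boundary
    fits (p0 > 0.99, where theta is unidentifiable).
    """

    params: TemplateParams
    sse: float
    n: int
    group: str
    sigma: float
    converged: bool
    evaluations: int
    ill_conditioned: bool


@dataclass(frozen=True)
class GoodnessOfFit:
    """Per-integer CDF residual table and the maximal |CDF difference|."""

    residuals: pd.DataFrame
    max_abs_cdf_diff: float


def _empirical_cdf(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    v = np.sort(values)
    return np.searchsorted(v, grid, side="right") / v.size


def _fit_grid(values: np.ndarray, sigma: float) -> np.ndarray:
    pad = int(np.ceil(3.0 * sigma))
    return np.arange(int(values.min()) - pad, int(values.max()) + pad + 1)


def _unpack(z: np.ndarray) -> TemplateParams:
    return TemplateParams(
        p0=float(expit(z[0])),
        theta=float(np.exp(np.clip(z[1], _LOG_THETA_MIN, _LOG_THETA_MAX))),
    )


def fit_template(
    mtr_values,
    err: ErrorModel,
    init: TemplateParams = TemplateParams(0.5, 3.0),
    group: str = "all",
    max_evaluations: int = 2000,
) -> FitResult:
    """Fit (p0, theta) to integer MTR samples by least squares on CDFs.

    Parameters
    ----------
    mtr_values : array-like of int
        Observed MTR values (pre-test vs hour 4), one per case.
    err : ErrorModel
        The fixed measurement-error model (SD from the error analysis).
    init : TemplateParams
        Starting point; three deterministic jitters of it are tried and
        the best final objective wins.
    """
    values = np.asarray(mtr_values)
    if values.size == 0:
        raise ValueError("mtr_values must not be empty")
    if not np.allclose(values, np.round(values)):
        raise ValueError("MTR values must be integers")
    values = values.astype(int)
    if values.size < 20:
        warnings.warn(
            f"fitting {values.size} MTR values (< 20): fit is ill-conditioned",
            stacklevel=2,
        )

    sigma = err.sigma
    grid = _fit_grid(values, sigma)
    emp = _empirical_cdf(values, grid)

    def objective(z: np.ndarray) -> float:
        params = _unpack(z)
        model = model_cdf_on_grid(build_template(params), sigma, grid)
        return float(np.sum((model - emp) ** 2))

    z0 = np.array(
        [float(logit(np.clip(init.p0, 1e-4, 1 - 1e-4))), float(np.log(init.theta))]
    )
    best = None
    evaluations = 0
    converged = False
    for jitter in _JITTERS:
        res = minimize(
            objective,
            z0 + np.asarray(jitter),
            method="Nelder-Mead",
            options={"maxfev": max_evaluations, "xatol": 1e-6, "fatol": 1e-12},
        )
        evaluations += int(res.nfev)
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    params = _unpack(best.x)
    return FitResult(
        params=params,
        sse=float(best.fun),
        n=int(values.size),
        group=group,
        sigma=float(sigma),
        converged=converged,
        evaluations=evaluations,
        ill_conditioned=(values.size < 20) or (params.p0 > 0.99),
    )


def goodness_of_fit(result: FitResult, mtr_values) -> GoodnessOfFit:
    """CDF residuals (model minus data) of a fit on its own grid."""
    values = np.asarray(mtr_values, dtype=int)
    grid = _fit_grid(values, result.sigma)
    emp = _empirical_cdf(values, grid)
    model = model_cdf_on_grid(build_template(result.params), result.sigma, grid)
    table = pd.DataFrame(
        {
            "mtr_db": grid,
            "model_cdf": model,
            "empirical_cdf": emp,
            "residual": model - emp,
        }
    )
    return GoodnessOfFit(table, float(np.abs(model - emp).max()))
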