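"""Nonlinear least-squares fitting of the adjusted Bernoulli power law.

The model ``TPG = c · AVA^alpha · Q^beta · v²`` is fitted in its reduced
form ``TPG = c' · AVA^a' · Q^b'`` (``c' = 100c``, ``a' = alpha - 2``,
``b' = beta + 2``) by plain (unweighted) nonlinear least squares with a
trust-region-reflective solver, initialised from ordinary least squares
on the log-log linearisation. Confidence intervals are Wald-type, from
the linearised covariance ``s²(JᵀJ)⁻¹`` with a t quantile at n-3 degrees
of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .hemodynamics import ModelCoefficients

__all__ = [
    "FitSettings",
    "FitResult",
    "IdentifiabilityError",
    "fit_power_law",
    "fit_cohort",
    "confidence_intervals",
    "predict",
]


class IdentifiabilityError(ValueError):
    """The design carries no information to separate the model parameters."""


@dataclass(frozen=True)
class FitSettings:
    """Solver and inference settings for :func:`fit_power_law`."""

    ftol: float = 1e-10  # relative reduction of the cost for convergence
    xtol: float = 1e-10  # relative parameter step for convergence
    gtol: float = 1e-10  # gradient-norm criterion
    max_iter: int = 500  # cap on residual evaluations of the solver
    ci_level: float = 0.95  # confidence level for Wald intervals


@dataclass
class FitResult:
    """Fitted coefficients plus goodness-of-fit and solver diagnostics.

    ``residuals`` are predicted minus observed gradients [mmHg];
    ``see`` is the residual standard error with n-3 degrees of freedom.
    """

    coefficients: ModelCoefficients
    r2: float
    see: float
    residuals: np.ndarray
    n: int
    converged: bool
    iterations: int
    objective_init: float
    objective_final: float
    # internals needed for Wald inference (reduced parameterisation)
    reduced_params: np.ndarray = field(repr=False, default=None)
    cov_reduced: Optional[np.ndarray] = field(repr=False, default=None)

    @property
    def residual_mean(self) -> float:
        return float(np.mean(self.residuals))

    @property
    def residual_sd(self) -> float:
        return float(np.std(self.residuals, ddof=1))

    def summary(self) -> dict:
        """Flat key-value representation suitable for JSON reports."""
        co = self.coefficients
        out = {
            "c": co.c,
            "alpha": co.alpha,
            "beta": co.beta,
            "r2": self.r2,
            "see_mmhg": self.see,
            "n": self.n,
            "converged": self.converged,
            "iterations": self.iterations,
            "residual_mean_mmhg": self.residual_mean,
            "residual_sd_mmhg": self.residual_sd,
        }
        for name, ci in (("c", co.ci_c), ("alpha", co.ci_alpha), ("beta", co.ci_beta)):
            if ci is not None:
                out[f"ci_{name}_low"], out[f"ci_{name}_high"] = ci
        return out


def _as_columns(ava, q, tpg):
    ava = np.asarray(ava, dtype=float)
    q = np.asarray(q, dtype=float)
    tpg = np.asarray(tpg, dtype=float)
    if not (ava.shape == q.shape == tpg.shape) or ava.ndim != 1:
        raise ValueError("ava, q and tpg must be one-dimensional arrays of equal length")
    if not np.all(np.isfinite(ava) & np.isfinite(q) & np.isfinite(tpg)):
        raise ValueError("non-finite value in training data")
    if np.any(ava <= 0):
        raise ValueError(f"non-positive AVA at rows {np.flatnonzero(ava <= 0).tolist()}")
    if np.any(q <= 0):
        raise ValueError(f"non-positive flow rate at rows {np.flatnonzero(q <= 0).tolist()}")
    return ava, q, tpg


def _loglog_init(ava: np.ndarray, q: np.ndarray, tpg: np.ndarray) -> np.ndarray:
    """OLS on log TPG = log c' + a'·log AVA + b'·log Q; drops TPG <= 0 rows."""
    keep = tpg > 0
    if keep.sum() < 3:
        # not enough positive responses to linearise; start at the clinical
        # Bernoulli point (c=4, alpha=0, beta=0 in full form)
        return np.array([400.0, -2.0, 2.0])
    design = np.column_stack(
        [np.ones(keep.sum()), np.log(ava[keep]), np.log(q[keep])]
    )
    coef, *_ = np.linalg.lstsq(design, np.log(tpg[keep]), rcond=None)
    return np.array([np.exp(coef[0]), coef[1], coef[2]])


def fit_power_law(
    ava: Sequence[float],
    q: Sequence[float],
    tpg: Sequence[float],
    settings: FitSettings = FitSettings(),
) -> FitResult:
    """Fit ``TPG = c'·AVA^a'·Q^b'`` and report full-form (c, alpha, beta).

    Parameters are unbounded; the loss is plain squared error. Returns a
    flagged (``converged=False``) result rather than raising when the
    solver stops on its iteration cap.

    Raises
    ------
    ValueError
        On fewer than 4 records or invalid values.
    IdentifiabilityError
        When all AVA are equal and all Q are equal (the two regressors
        are constants and the exponents are undetermined).
    """
    ava, q, tpg = _as_columns(ava, q, tpg)
    n = ava.size
    if n < 4:
        raise ValueError(f"need at least 4 records to fit 3 parameters, got {n}")
    if np.ptp(ava) == 0.0 and np.ptp(q) == 0.0:
        raise IdentifiabilityError(
            "all AVA equal and all Q equal: power-law exponents are not identifiable"
        )

    log_ava, log_q = np.log(ava), np.log(q)

    def model(p: np.ndarray) -> np.ndarray:
        cr, ar, br = p
        return cr * np.exp(ar * log_ava + br * log_q)

    def resid(p: np.ndarray) -> np.ndarray:
        return model(p) - tpg

    p0 = _loglog_init(ava, q, tpg)
    objective_init = float(0.5 * np.sum(resid(p0) ** 2))

    sol = optimize.least_squares(
        resid,
        p0,
        method="trf",
        ftol=settings.ftol,
        xtol=settings.xtol,
        gtol=settings.gtol,
        max_nfev=settings.max_iter,
    )

    residuals = sol.fun  # predicted - truth
    sse = float(np.sum(residuals**2))
    sst = float(np.sum((tpg - tpg.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    dof = n - 3
    see = float(np.sqrt(sse / dof))

    # linearised covariance of the reduced parameters
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * (sse / dof)
    except np.linalg.LinAlgError:
        cov = None

    cr, ar, br = sol.x
    coefficients = ModelCoefficients.from_reduced(cr, ar, br)

    return FitResult(
        coefficients=coefficients,
        r2=max(0.0, min(1.0, r2)),
        see=see,
        residuals=residuals,
        n=n,
        converged=bool(sol.success and sol.status != 0),
        iterations=int(sol.nfev),
        objective_init=objective_init,
        objective_final=float(sol.cost),
        reduced_params=sol.x,
        cov_reduced=cov,
    )


def fit_cohort(cohort: pd.DataFrame, settings: FitSettings = FitSettings()) -> FitResult:
    """Fit the power law on the retained rows of a cohort table.

    Expects the canonical cohort schema (``ava_cm2``, ``q_l_s``,
    ``tpg_true_mmhg``, boolean ``excluded``); flagged rows are dropped and
    the ground-truth gradient must be non-negative.
    """
    retained = cohort.loc[~cohort["excluded"].astype(bool)]
    tpg = retained["tpg_true_mmhg"].to_numpy(dtype=float)
    if np.any(tpg < 0):
        raise ValueError("negative ground-truth TPG in cohort table")
    return fit_power_law(
        retained["ava_cm2"].to_numpy(dtype=float),
        retained["q_l_s"].to_numpy(dtype=float),
        tpg,
        settings,
    )


def confidence_intervals(fit: FitResult, level: float = 0.95) -> ModelCoefficients:
    """Wald confidence intervals for (c, alpha, beta) at the given level.

    Intervals are computed in the reduced parameterisation from the
    linearised covariance with a t quantile at n-3 degrees of freedom and
    mapped to the full form (division by 100 for c, unit shifts for the
    exponents — both linear, so the intervals transform exactly).
    """
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    if fit.cov_reduced is None:
        raise IdentifiabilityError("singular Jacobian: covariance unavailable")
    se = np.sqrt(np.diag(fit.cov_reduced))
    if not np.all(np.isfinite(se)):
        raise IdentifiabilityError("non-finite standard errors: covariance unavailable")
    tq = stats.t.ppf(0.5 + level / 2.0, df=fit.n - 3)
    lo = fit.reduced_params - tq * se
    hi = fit.reduced_params + tq * se
    co = fit.coefficients
    return ModelCoefficients(
        c=co.c,
        alpha=co.alpha,
        beta=co.beta,
        ci_c=(lo[0] / 100.0, hi[0] / 100.0),
        ci_alpha=(lo[1] + 2.0, hi[1] + 2.0),
        ci_beta=(lo[2] - 2.0, hi[2] - 2.0),
    )


def predict(coeffs: ModelCoefficients, ava, q) -> np.ndarray:
    """Vectorised adjusted-model gradient for arrays of AVA [cm²] and Q [l/s].

    Order-preserving elementwise map; zero flow yields 0 mmHg.
    """
    ava = np.asarray(ava, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(ava <= 0):
        raise ValueError(f"non-positive AVA at rows {np.flatnonzero(ava <= 0).tolist()}")
    out = np.zeros(np.broadcast(ava, q).shape)
    nz = q != 0
    av, qv = np.broadcast_arrays(ava, q)
    out[nz] = (
        coeffs.c_reduced * av[nz] ** coeffs.alpha_reduced * qv[nz] ** coeffs.beta_reduced
    )
    return out
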