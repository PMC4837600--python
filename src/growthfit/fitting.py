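"""Nonlinear least-squares estimation of the logistic parameters.

Given a background-corrected time series, :func:`fit_logistic` estimates
(K, r, N0) by minimising the sum of squared residuals

.. math:: \\sum_i \\left(y_i - N(t_i; K, r, N_0)\\right)^2

with a bounded trust-region-reflective solver (scipy's ``least_squares``),
starting from a data-driven initial guess.  Box constraints keep the
solver out of pathological corners (flat wells otherwise diverge); for
well-behaved data the constrained optimum coincides with the classical
unconstrained Levenberg-Marquardt one.

Non-convergence is data, not an exception: in batch contexts one bad well
must not kill a plate, so degenerate or unfittable wells come back as a
:class:`GrowthFitResult` with ``converged=False`` and a diagnostic note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateSampleError, InvalidInputError, InvalidIntervalError
from .model import LogisticParameters, doubling_time, empirical_auc, logistic_auc, logistic_value
from .preprocess import (
    CorrectionMode,
    GrowthSample,
    subtract_blank_series,
    subtract_min_background,
)

__all__ = ["GrowthFitResult", "initial_guess", "fit_logistic", "summarize_growth"]

#: Default cap on the fitted growth rate, per time unit.  Prevents
#: near-step-function fits on pathological wells; configurable per call.
DEFAULT_R_MAX = 20.0

#: Upper box constraint on K as a multiple of the maximum reading.  Large
#: enough not to bind when a slow curve is still far from its plateau at
#: the end of the run (a tight cap there excludes the true K); finite so
#: the solver cannot wander into overflow territory.
DEFAULT_K_MAX_FACTOR = 1e6

# Solver controls, frozen: relative cost tolerance and parameter tolerance
# 1e-10, at most 1000 residual evaluations.
_FTOL = 1e-10
_XTOL = 1e-10
_MAX_NFEV = 1000


@dataclass(frozen=True)
class GrowthFitResult:
    """A fitted well: parameters, uncertainties, and derived growth metrics.

    Attributes
    ----------
    well_id : str
        Label of the well this result describes.
    converged : bool
        Whether the fit succeeded.  When False, all metric fields are
        None and ``note`` explains why.
    params : LogisticParameters or None
        The fitted (K, r, N0).
    stderr_K, stderr_r, stderr_N0 : float or None
        Standard errors from the Jacobian-based covariance estimate
        sigma^2 (J^T J)^-1; None when the Jacobian is rank-deficient.
    sigma : float or None
        Residual standard error, sqrt(RSS / dof), in reading units.
    dof : int or None
        Residual degrees of freedom: number of fitted points minus 3.
    t_mid : float or None
        Inflection time at which N = K/2 (NaN for declining curves).
    t_dt : float or None
        Fastest doubling time, ln 2 / r.
    auc_l : float or None
        Area under the fitted logistic curve over the AUC window.
    auc_e : float or None
        Trapezoid-rule area under the corrected readings, same window.
    note : str
        Free-text diagnostics ("" when nothing noteworthy).
    """

    well_id: str
    converged: bool
    params: LogisticParameters | None = None
    stderr_K: float | None = None
    stderr_r: float | None = None
    stderr_N0: float | None = None
    sigma: float | None = None
    dof: int | None = None
    t_mid: float | None = None
    t_dt: float | None = None
    auc_l: float | None = None
    auc_e: float | None = None
    note: str = ""


def initial_guess(times, values) -> LogisticParameters:
    """Data-driven starting point for the logistic fit.

    K starts at the maximum reading and N0 at the first reading (floored
    at eps = 1e-6 * max so the zeros created by min-subtraction do not
    break the parameterisation).  r starts at the slope of a straight
    line through ln(values + eps) versus time over the early-exponential
    points — those between 10 % and 50 % of the maximum — falling back
    to 1 per time unit when fewer than 3 such points exist or the slope
    is not positive.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise InvalidInputError("times and values must be 1-d and the same length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        raise InvalidInputError("times and values must be finite")
    if t.size < 4:
        raise InvalidInputError("initial guess needs at least 4 points")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    v_max = float(np.max(v))
    if v_max <= 0:
        raise DegenerateSampleError("all readings are zero or negative")
    eps = 1e-6 * v_max
    K0 = v_max
    N00 = max(float(v[0]), eps)
    window = (v >= 0.1 * v_max) & (v <= 0.5 * v_max)
    r0 = 1.0
    if int(np.sum(window)) >= 3:
        slope = np.polyfit(t[window], np.log(v[window] + eps), 1)[0]
        if np.isfinite(slope) and slope > 0:
            r0 = float(slope)
    return LogisticParameters(K=K0, r=r0, N0=N00)


def _degenerate_note(v: np.ndarray) -> str | None:
    """Classify signals that cannot support a growth fit."""
    if np.max(v) <= 0:
        return "degenerate data: readings all zero or negative"
    if np.ptp(v) == 0:
        return "degenerate data: constant readings"
    diffs = np.diff(v)
    if np.all(diffs <= 0):
        return "degenerate data: monotone decreasing signal"
    return None


def _covariance_stderr(jac: np.ndarray, sigma2: float) -> tuple[float, float, float] | None:
    """Standard errors from sigma^2 (J^T J)^-1, or None if rank-deficient."""
    _, s, VT = np.linalg.svd(jac, full_matrices=False)
    threshold = np.finfo(float).eps * max(jac.shape) * s[0] if s.size else 0.0
    if s.size < 3 or s[-1] <= threshold:
        return None
    cov = (VT.T / s**2) @ VT * sigma2
    diag = np.diag(cov)
    if np.any(diag < 0):
        return None
    se = np.sqrt(diag)
    return float(se[0]), float(se[1]), float(se[2])


def fit_logistic(
    sample: GrowthSample,
    r_max: float = DEFAULT_R_MAX,
    t_auc_end: float | None = None,
    k_max_factor: float = DEFAULT_K_MAX_FACTOR,
) -> GrowthFitResult:
    """Fit the logistic equation to a corrected sample and derive all metrics.

    Parameters
    ----------
    sample : GrowthSample
        Must carry corrected readings (apply a preprocessing step first,
        or use :func:`summarize_growth` which does so for you) and at
        least 5 points.
    r_max : float
        Upper box constraint on the growth rate, per time unit.
    t_auc_end : float, optional
        Right edge of the AUC window; defaults to the last time point.

    Returns
    -------
    GrowthFitResult
        With ``converged=False`` and a note (never an exception) on
        degenerate data or optimizer failure.
    """
    if sample.corrected is None:
        raise InvalidInputError(
            f"well {sample.well_id!r}: corrected readings required before fitting"
        )
    t = sample.times
    y = sample.corrected
    if t.size < 5:
        raise InvalidInputError(
            f"well {sample.well_id!r}: fitting needs at least 5 points, got {t.size}"
        )
    if t_auc_end is None:
        t_auc_end = float(t[-1])
    elif not (t[0] <= t_auc_end <= t[-1]):
        raise InvalidIntervalError(
            f"t_auc_end ({t_auc_end!r}) outside the data range [{t[0]!r}, {t[-1]!r}]"
        )

    note = _degenerate_note(y)
    if note is not None:
        return GrowthFitResult(well_id=sample.well_id, converged=False, note=note)

    guess = initial_guess(t, y)
    y_max = float(np.max(y))
    eps = 1e-6 * y_max
    lower = np.array([eps, eps, eps])
    upper = np.array([k_max_factor * y_max, r_max, y_max])
    x0 = np.clip([guess.K, guess.r, guess.N0], lower, upper)

    def residuals(p: np.ndarray) -> np.ndarray:
        K, r, N0 = p
        return logistic_value(LogisticParameters(K=K, r=r, N0=N0), t) - y

    try:
        res = least_squares(
            residuals,
            x0,
            bounds=(lower, upper),
            method="trf",
            ftol=_FTOL,
            xtol=_XTOL,
            gtol=1e-12,
            max_nfev=_MAX_NFEV,
        )
    except Exception as exc:  # optimizer blow-up is data, not a crash
        return GrowthFitResult(
            well_id=sample.well_id, converged=False, note=f"optimizer error: {exc}"
        )
    if not res.success:
        return GrowthFitResult(
            well_id=sample.well_id,
            converged=False,
            note=f"optimizer did not converge: {res.message}",
        )

    K_hat, r_hat, N0_hat = (float(x) for x in res.x)
    params = LogisticParameters(K=K_hat, r=r_hat, N0=N0_hat)
    n = int(t.size)
    dof = n - 3
    rss = float(np.sum(res.fun**2))
    sigma = math.sqrt(rss / dof) if dof > 0 else float("nan")
    se = _covariance_stderr(res.jac, sigma**2) if dof > 0 else None

    notes: list[str] = []
    if params.is_declining:
        notes.append("declining fit: N0 > K")
    if se is None:
        notes.append("standard errors unavailable (rank-deficient Jacobian)")

    return GrowthFitResult(
        well_id=sample.well_id,
        converged=True,
        params=params,
        stderr_K=se[0] if se else None,
        stderr_r=se[1] if se else None,
        stderr_N0=se[2] if se else None,
        sigma=sigma,
        dof=dof,
        t_mid=params.t_mid,
        t_dt=doubling_time(r_hat),
        auc_l=logistic_auc(params, float(t[0]), t_auc_end),
        auc_e=empirical_auc(t, y, t_auc_end),
        note="; ".join(notes),
    )


def summarize_growth(
    sample: GrowthSample,
    t_auc_end: float | None = None,
    correction: CorrectionMode | str = CorrectionMode.MIN_VALUE,
    blank=None,
    r_max: float = DEFAULT_R_MAX,
) -> GrowthFitResult:
    """One-call pipeline: background-correct, fit, and assemble all metrics.

    Applies the configured background correction (default: subtract the
    per-well minimum) unless the sample already carries corrected
    readings, then fits and computes doubling time, inflection time, and
    both AUCs over [first time, ``t_auc_end`` or last time].
    """
    mode = CorrectionMode(correction)
    if sample.corrected is None:
        if mode is CorrectionMode.MIN_VALUE:
            sample = subtract_min_background(sample)
        elif mode is CorrectionMode.BLANK_SERIES:
            if blank is None:
                raise InvalidInputError("blank_series correction requires a blank vector")
            sample = subtract_blank_series(sample, blank)
        else:
            sample = GrowthSample(
                well_id=sample.well_id,
                times=sample.times,
                raw=sample.raw,
                corrected=sample.raw.copy(),
                correction_applied=CorrectionMode.NONE,
            )
    return fit_logistic(sample, r_max=r_max, t_auc_end=t_auc_end)
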