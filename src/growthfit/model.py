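"""Logistic growth model: trajectory, doubling time, and areas under the curve.

The model is the standard logistic equation of population ecology,

.. math::

    N(t) = \\frac{K}{1 + \\left(\\frac{K - N_0}{N_0}\\right) e^{-rt}},

where ``K`` is the carrying capacity (the upper asymptote, in the same
units as the readings — typically OD600), ``N0`` the population size at
``t = 0``, and ``r`` the intrinsic per-capita growth rate in inverse time
units.  All outputs inherit the unit of the input times: fit a curve
recorded in hours and ``r`` is per hour, the doubling time in hours.

Everything here is a pure function of its arguments; no fitting, no I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidIntervalError,
    NonPositiveRateError,
)

__all__ = [
    "LogisticParameters",
    "logistic_value",
    "doubling_time",
    "logistic_auc",
    "empirical_auc",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class LogisticParameters:
    """The fitted triple (K, r, N0) of the logistic growth equation.

    Parameters
    ----------
    K : float
        Carrying capacity, in reading units (absorbance or cells). > 0.
    r : float
        Intrinsic growth rate, in inverse time units. Finite; > 0 for a
        growing population.
    N0 : float
        Population size at time zero, same units as ``K``. > 0.

    Notes
    -----
    ``N0 > K`` describes a declining curve.  It is permitted (noisy flat
    wells can land there) and exposed via :attr:`is_declining` so callers
    can flag rather than crash.
    """

    K: float
    r: float
    N0: float

    def __post_init__(self) -> None:
        for name, v in (("K", self.K), ("r", self.r), ("N0", self.N0)):
            if not math.isfinite(v):
                raise InvalidInputError(f"{name} must be finite, got {v!r}")
        if self.K <= 0:
            raise InvalidInputError(f"K must be > 0, got {self.K!r}")
        if self.N0 <= 0:
            raise InvalidInputError(f"N0 must be > 0, got {self.N0!r}")

    @property
    def shape_coefficient(self) -> float:
        """A = (K - N0) / N0, the coefficient of e^(-rt) in the denominator."""
        return (self.K - self.N0) / self.N0

    @property
    def is_declining(self) -> bool:
        """True when N0 > K, i.e. the curve decreases toward K."""
        return self.N0 > self.K

    @property
    def t_mid(self) -> float:
        """Inflection time, at which N = K/2.  NaN for declining curves."""
        A = self.shape_coefficient
        if A <= 0 or self.r == 0:
            return math.nan
        return math.log(A) / self.r


def logistic_value(params: LogisticParameters, t):
    """Evaluate the logistic trajectory N(t).

    Parameters
    ----------
    params : LogisticParameters
    t : float or array-like
        Time(s) at which to evaluate; negative values extrapolate backward.

    Returns
    -------
    float or ndarray
        N(t) = K / (1 + A e^(-rt)) with A = (K - N0)/N0.  Strictly
        increasing in t and bounded in (0, K) when 0 < N0 < K and r > 0.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise InvalidInputError("t must be finite")
    A = params.shape_coefficient
    z = -params.r * t_arr
    # For large positive z, e^z overflows though N -> 0; rewrite as
    # K e^{-z} / (e^{-z} + A), which is safe on that branch (A >= 0 there
    # whenever the curve is growing; for A < 0 the plain form is safe for
    # z <= 0 and the rewritten form for z > 0 only while e^{-z} > |A|).
    with np.errstate(over="ignore", invalid="ignore"):
        plain = params.K / (1.0 + A * np.exp(z))
        flipped = params.K * np.exp(-z) / (np.exp(-z) + A)
    out = np.where(z > 0, flipped, plain)
    if out.ndim == 0:
        return float(out)
    return out


def doubling_time(r: float) -> float:
    """Fastest possible doubling time, t_DT = ln 2 / r.

    This is the generation time the population would have with no density
    limitation, i.e. far from carrying capacity.

    Raises
    ------
    InvalidInputError
        If ``r`` is not finite.
    NonPositiveRateError
        If ``r <= 0`` (the population never doubles).
    """
    if not math.isfinite(r):
        raise InvalidInputError(f"growth rate must be finite, got {r!r}")
    if r <= 0:
        raise NonPositiveRateError(f"doubling time undefined for r <= 0 (r={r!r})")
    return LN2 / r


def _log_denominator(params: LogisticParameters, t: float) -> float:
    """ln(e^(rt) + A), computed without overflowing e^(rt).

    For A > 0 this is logaddexp(rt, ln A); for A < 0 (declining curve) the
    identity rt + log1p(A e^(-rt)) is used, valid while A e^(-rt) > -1.
    """
    A = params.shape_coefficient
    rt = params.r * t
    if A > 0:
        return float(np.logaddexp(rt, math.log(A)))
    if A == 0:
        return rt
    x = A * math.exp(-rt)
    if x <= -1:
        raise InvalidInputError(
            "logistic antiderivative is singular on this interval "
            f"(declining curve, t={t!r})"
        )
    return rt + math.log1p(x)


def logistic_auc(params: LogisticParameters, t_start: float, t_end: float) -> float:
    """Area under the logistic curve over [t_start, t_end], in closed form.

    The antiderivative of N(t) is (K/r) ln(e^(rt) + A); the definite
    integral is that expression evaluated at the endpoints.  The log term
    is computed as rt + ln(1 + A e^(-rt)) to avoid overflow of e^(rt) for
    large rt (routine when rates are per minute over a day-long run).

    Raises
    ------
    InvalidIntervalError
        If ``t_end < t_start``.
    """
    for name, v in (("t_start", t_start), ("t_end", t_end)):
        if not math.isfinite(v):
            raise InvalidInputError(f"{name} must be finite, got {v!r}")
    if t_end < t_start:
        raise InvalidIntervalError(f"t_end ({t_end!r}) < t_start ({t_start!r})")
    if t_end == t_start:
        return 0.0
    if params.r == 0 or params.K == params.N0:
        # constant integrand N(t) = N0
        return params.N0 * (t_end - t_start)
    scale = params.K / params.r
    return scale * (_log_denominator(params, t_end) - _log_denominator(params, t_start))


def empirical_auc(times, values, t_end: float | None = None) -> float:
    """Trapezoid-rule area under observed readings from the first time to t_end.

    Sums the areas of the trapezoids formed by connecting consecutive data
    points.  When ``t_end`` falls between two sample times, the final
    trapezoid is truncated by linear interpolation to ``t_end``; points
    beyond ``t_end`` are excluded.

    Parameters
    ----------
    times : array-like
        Strictly increasing sample times.
    values : array-like
        Readings at those times (same length, >= 2 points).
    t_end : float, optional
        Right edge of the integration window; defaults to the last sample
        time and must not exceed it.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
        raise InvalidInputError("times and values must be 1-d and the same length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        raise InvalidInputError("times and values must be finite")
    if t.size < 2:
        raise InsufficientDataError("empirical AUC needs at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("times must be strictly increasing without duplicates")
    if t_end is None:
        t_end = float(t[-1])
    if not math.isfinite(t_end):
        raise InvalidInputError(f"t_end must be finite, got {t_end!r}")
    if t_end > t[-1]:
        raise InvalidIntervalError(
            f"t_end ({t_end!r}) exceeds the last sample time ({t[-1]!r})"
        )
    if t_end < t[0]:
        raise InvalidIntervalError(
            f"t_end ({t_end!r}) precedes the first sample time ({t[0]!r})"
        )
    if t_end == t[0]:
        return 0.0
    keep = t <= t_end
    tt, vv = t[keep], v[keep]
    if tt[-1] < t_end:
        v_end = float(np.interp(t_end, t, v))
        tt = np.append(tt, t_end)
        vv = np.append(vv, v_end)
    if tt.size < 2:
        raise InsufficientDataError("fewer than 2 usable points in the AUC window")
    return float(np.trapezoid(vv, tt))
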