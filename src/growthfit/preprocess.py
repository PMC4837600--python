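"""Background correction of raw plate-reader readings.

The media itself absorbs light, so raw OD readings carry a constant
offset that must be removed before fitting.  Two mutually exclusive modes
are provided:

* ``min_value`` (the default): subtract the per-well minimum reading, so
  the corrected minimum is exactly zero.  Requires no extra well and is
  the mode used throughout the package's own analyses.
* ``blank_series``: subtract a media-only blank well, point by point.
  Negative corrected values are retained (clipping would bias the many
  information-poor early-time points); a flag records their presence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "CorrectionMode",
    "GrowthSample",
    "subtract_min_background",
    "subtract_blank_series",
]


class CorrectionMode(str, enum.Enum):
    """Which background correction has been applied to a sample."""

    NONE = "none"
    MIN_VALUE = "min_value"
    BLANK_SERIES = "blank_series"


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be 1-dimensional")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class GrowthSample:
    """One well's time series: times, raw readings, optional corrected readings.

    ``times`` must be strictly increasing; at least 5 points are
    recommended for a meaningful three-parameter fit.  ``corrected`` is
    absent (None) until a correction is applied; ``correction_applied``
    records which mode produced it.  ``has_negative`` is set when
    blank-series correction produced negative values.
    """

    well_id: str
    times: np.ndarray
    raw: np.ndarray
    corrected: np.ndarray | None = None
    correction_applied: CorrectionMode = CorrectionMode.NONE
    has_negative: bool = field(default=False)

    def __post_init__(self) -> None:
        times = _as_vector(self.times, "times")
        raw = _as_vector(self.raw, "raw")
        if times.shape != raw.shape:
            raise InvalidInputError("times and raw must be the same length")
        if times.size == 0:
            raise InvalidInputError("sample must contain at least one point")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "raw", raw)
        if self.corrected is not None:
            corr = _as_vector(self.corrected, "corrected")
            if corr.shape != raw.shape:
                raise InvalidInputError("corrected must match raw in length")
            object.__setattr__(self, "corrected", corr)

    @property
    def readings(self) -> np.ndarray:
        """Corrected readings when present, raw otherwise."""
        return self.raw if self.corrected is None else self.corrected

    def __len__(self) -> int:
        return int(self.times.size)


def subtract_min_background(sample: GrowthSample) -> GrowthSample:
    """Subtract the minimum observed reading of this well from all readings.

    The corrected series has minimum exactly 0; applying the correction
    twice is the same as applying it once (idempotent).  This is the
    automatic correction mode: it needs no blank well and removes any
    constant media offset, leaving the fitted K and r unchanged by that
    offset.
    """
    corrected = sample.raw - float(np.min(sample.raw))
    return replace(
        sample,
        corrected=corrected,
        correction_applied=CorrectionMode.MIN_VALUE,
        has_negative=False,
    )


def subtract_blank_series(sample: GrowthSample, blank) -> GrowthSample:
    """Subtract a media-only blank well's readings, point by point.

    Negative corrected values are *not* clipped; ``has_negative`` is set
    so downstream fitting can account for them (its N0 lower bound
    absorbs slightly negative early points).
    """
    blank_arr = _as_vector(blank, "blank")
    if blank_arr.shape != sample.raw.shape:
        raise InvalidInputError(
            f"blank length {blank_arr.size} does not match raw length {sample.raw.size}"
        )
    corrected = sample.raw - blank_arr
    return replace(
        sample,
        corrected=corrected,
        correction_applied=CorrectionMode.BLANK_SERIES,
        has_negative=bool(np.any(corrected < 0)),
    )
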