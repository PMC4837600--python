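"""Synthetic logistic growth curves and plates with known ground truth.

Emulates a plate-reader acquisition: readings on a regular grid
(default: every 10 minutes for 24 hours, i.e. 145 points when times are
in hours), equal to the logistic trajectory plus a constant background
offset (the media's absorbance) plus additive Gaussian noise.  Negative
noisy readings are kept — truncating them would bias the noise model —
and min-value background correction handles them downstream.

The generator is the ground-truth oracle for the package's tests: fit a
generated curve and you know exactly what the estimates should be.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .model import LogisticParameters, logistic_value
from .preprocess import GrowthSample
from .plate import PlateTable

__all__ = ["SyntheticCurveSpec", "generate_curve", "generate_plate"]


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Ground truth and noise model for one synthetic growth curve.

    Parameters
    ----------
    K, r, N0 : float
        True logistic parameters (reading units; r per time unit).
    t_start, t_end, dt : float
        Sampling window and interval, in time units.  The grid is
        ``t_start + k*dt`` for all k with ``t_start + k*dt <= t_end``.
    noise_sd : float
        Standard deviation of the additive Gaussian reading noise
        (0.005 is typical OD600 instrument noise).
    background : float
        Constant additive offset emulating media absorbance.
    seed : int
        Seed for the per-curve random generator.
    """

    K: float = 0.5
    r: float = 1.0
    N0: float = 0.001
    t_start: float = 0.0
    t_end: float = 24.0
    dt: float = 1.0 / 6.0
    noise_sd: float = 0.0
    background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        LogisticParameters(K=self.K, r=self.r, N0=self.N0)  # validates
        if not self.dt > 0:
            raise InvalidInputError(f"dt must be > 0, got {self.dt!r}")
        if not self.t_end > self.t_start:
            raise InvalidInputError("t_end must exceed t_start")
        if self.noise_sd < 0:
            raise InvalidInputError(f"noise_sd must be >= 0, got {self.noise_sd!r}")
        if self.background < 0:
            raise InvalidInputError(f"background must be >= 0, got {self.background!r}")

    @property
    def params(self) -> LogisticParameters:
        return LogisticParameters(K=self.K, r=self.r, N0=self.N0)

    @property
    def times(self) -> np.ndarray:
        n = int(np.floor((self.t_end - self.t_start) / self.dt + 1e-9)) + 1
        return self.t_start + self.dt * np.arange(n)


def generate_curve(spec: SyntheticCurveSpec, rng: np.random.Generator | None = None) -> GrowthSample:
    """Simulate one well: logistic trajectory + background + Gaussian noise.

    Deterministic given ``spec.seed`` (an explicit ``rng`` overrides the
    seed; :func:`generate_plate` uses this to hand each well its own
    stream).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t = spec.times
    truth = logistic_value(spec.params, t)
    noise = rng.normal(0.0, spec.noise_sd, size=t.size) if spec.noise_sd > 0 else 0.0
    return GrowthSample(well_id="synthetic", times=t, raw=truth + spec.background + noise)


def generate_plate(specs: dict[str, SyntheticCurveSpec], seed: int | None = None) -> PlateTable:
    """Simulate a whole plate of wells sharing one sampling grid.

    Per-well seeds are derived from the master ``seed`` by spawning one
    ``numpy.random.SeedSequence`` child per well, in well order; each
    well therefore gets an independent noise stream and the whole plate
    is reproducible from the single master seed.  When ``seed`` is None,
    each spec's own ``seed`` field is used instead.
    """
    if not specs:
        raise InvalidInputError("specs must contain at least one well")
    grids = [spec.times for spec in specs.values()]
    first = grids[0]
    for label, grid in zip(specs, grids):
        if grid.shape != first.shape or not np.allclose(grid, first):
            raise InvalidInputError(
                f"well {label!r} uses a different sampling grid than the first well"
            )
    if seed is not None:
        children = np.random.SeedSequence(seed).spawn(len(specs))
        rngs = [np.random.default_rng(child) for child in children]
    else:
        rngs = [np.random.default_rng(spec.seed) for spec in specs.values()]
    wells = {
        label: generate_curve(spec, rng=rng).raw
        for (label, spec), rng in zip(specs.items(), rngs)
    }
    return PlateTable(times=first, wells=wells)
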