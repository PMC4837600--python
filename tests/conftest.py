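import numpy as np
import pytest
from scipy.stats import rankdata

from growthfit import GrowthSample, LogisticParameters, SyntheticCurveSpec, generate_curve


def exact_spearman(x, y) -> float:
    """Spearman rho via the exact rank-difference formula.

    For tie-free data, 1 - 6*sum(d^2)/(n(n^2-1)) with integer rank
    differences d is exact in floating point, unlike a Pearson correlation
    of the ranks, which can land one ulp away from +/-1.
    """
    rx = rankdata(x)
    ry = rankdata(y)
    n = len(rx)
    d2 = float(np.sum((rx - ry) ** 2))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1.0))


@pytest.fixture
def standard_params() -> LogisticParameters:
    """A typical OD600-scale growing well."""
    return LogisticParameters(K=0.7, r=0.9, N0=0.005)


@pytest.fixture
def noiseless_sample(standard_params) -> GrowthSample:
    """Noiseless 10-min sampling over 24 h from the standard parameters."""
    spec = SyntheticCurveSpec(
        K=standard_params.K,
        r=standard_params.r,
        N0=standard_params.N0,
        noise_sd=0.0,
        background=0.0,
    )
    return generate_curve(spec)


@pytest.fixture
def param_grid():
    """A small deterministic sweep of biologically plausible parameters."""
    rng = np.random.default_rng(20240301)
    draws = []
    for _ in range(25):
        K = rng.uniform(0.1, 2.0)
        r = rng.uniform(0.1, 3.0)
        N0 = K * 10 ** rng.uniform(-4, np.log10(0.05))
        draws.append(LogisticParameters(K=K, r=r, N0=N0))
    return draws
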