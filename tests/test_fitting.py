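"""Nonlinear least-squares fitting: initial guess, recovery, diagnostics."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from conftest import exact_spearman

from growthfit import (
    DegenerateSampleError,
    GrowthSample,
    InvalidInputError,
    InvalidIntervalError,
    LogisticParameters,
    SyntheticCurveSpec,
    empirical_auc,
    fit_logistic,
    generate_curve,
    initial_guess,
    logistic_auc,
    logistic_value,
    subtract_min_background,
    summarize_growth,
)


def noiseless_sample(K, r, N0, dt=1 / 6, t_end=24.0):
    spec = SyntheticCurveSpec(K=K, r=r, N0=N0, dt=dt, t_end=t_end, noise_sd=0.0)
    s = generate_curve(spec)
    return GrowthSample(well_id=s.well_id, times=s.times, raw=s.raw, corrected=s.raw)


class TestInitialGuess:
    def test_guess_leads_fit_to_truth(self):
        s = noiseless_sample(K=1.0, r=1.0, N0=0.01)
        g = initial_guess(s.times, s.raw)
        assert g.K == pytest.approx(np.max(s.raw))
        res = fit_logistic(s)
        assert res.converged
        assert res.params.K == pytest.approx(1.0, rel=1e-6)

    def test_linear_ramp_gives_bounded_positive_guess(self):
        t = np.linspace(0, 10, 11)
        g = initial_guess(t, t / 10)
        assert g.K == pytest.approx(1.0)
        assert 0 < g.r < math.inf
        assert g.N0 > 0

    def test_flat_zero_well_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            initial_guess(np.arange(5.0), np.zeros(5))


class TestFitLogistic:
    def test_noiseless_recovery_to_high_precision(self):
        res = fit_logistic(noiseless_sample(K=0.7, r=0.9, N0=0.005))
        assert res.converged
        assert res.params.K == pytest.approx(0.7, rel=1e-6)
        assert res.params.r == pytest.approx(0.9, rel=1e-6)
        assert res.params.N0 == pytest.approx(0.005, rel=1e-6)

    def test_parameter_recovery_sweep(self, param_grid):
        """Noiseless fits over a plausible (K, r, N0) sweep recover all
        three parameters within relative 1e-5."""
        for p in param_grid:
            res = fit_logistic(noiseless_sample(p.K, p.r, p.N0))
            assert res.converged
            assert res.params.K == pytest.approx(p.K, rel=1e-5)
            assert res.params.r == pytest.approx(p.r, rel=1e-5)
            assert res.params.N0 == pytest.approx(p.N0, rel=1e-5)

    def test_noise_robustness_median_rate_error(self):
        """At typical OD noise (sd 0.005), the median relative error of the
        fitted growth rate over 100 seeded replicates stays below 2 %
        (threshold frozen from an independent pre-build simulation)."""
        spec_kw = dict(K=0.7, r=0.9, N0=0.005, noise_sd=0.005)
        errs = []
        for seed in range(100):
            s = generate_curve(SyntheticCurveSpec(seed=seed, **spec_kw))
            res = fit_logistic(subtract_min_background(s))
            errs.append(abs(res.params.r - 0.9) / 0.9 if res.converged else np.inf)
        assert float(np.median(errs)) < 0.02

    def test_rss_not_worse_than_initial_guess(self):
        s = generate_curve(SyntheticCurveSpec(K=0.5, r=1.2, N0=0.01, noise_sd=0.01, seed=3))
        s = subtract_min_background(s)
        g = initial_guess(s.times, s.corrected)
        rss0 = float(np.sum((logistic_value(g, s.times) - s.corrected) ** 2))
        res = fit_logistic(s)
        rss = float(np.sum((logistic_value(res.params, s.times) - s.corrected) ** 2))
        assert rss <= rss0 + 1e-15

    def test_constant_well_returns_nonconverged_not_exception(self):
        t = np.arange(10.0)
        s = GrowthSample(well_id="A1", times=t, raw=np.full(10, 0.2), corrected=np.full(10, 0.2))
        res = fit_logistic(s)
        assert not res.converged
        assert "constant" in res.note
        assert res.params is None and res.auc_l is None

    def test_monotone_decreasing_well_flagged(self):
        t = np.arange(10.0)
        v = np.linspace(0.5, 0.1, 10)
        s = GrowthSample(well_id="A1", times=t, raw=v, corrected=v)
        res = fit_logistic(s)
        assert not res.converged
        assert "decreasing" in res.note

    def test_requires_corrected_readings(self):
        s = generate_curve(SyntheticCurveSpec())
        with pytest.raises(InvalidInputError):
            fit_logistic(s)

    def test_diagnostics_consistency(self):
        s = generate_curve(SyntheticCurveSpec(K=0.7, r=0.9, N0=0.005, noise_sd=0.005, seed=9))
        res = fit_logistic(subtract_min_background(s))
        assert res.dof == len(s) - 3
        assert res.sigma > 0
        assert res.stderr_K > 0 and res.stderr_r > 0 and res.stderr_N0 > 0
        assert res.t_dt == pytest.approx(math.log(2) / res.params.r, rel=1e-15)
        # inflection time lands where the fitted curve crosses K/2
        assert logistic_value(res.params, res.t_mid) == pytest.approx(
            res.params.K / 2, rel=1e-12
        )

    def test_sigma_decreases_with_noise(self):
        # fit the uncorrected signal so the noiseless fit is exact and
        # sigma tracks only the injected noise
        sigmas = []
        for sd in (0.02, 0.01, 0.005, 0.0):
            s = generate_curve(SyntheticCurveSpec(K=0.7, r=0.9, N0=0.005, noise_sd=sd, seed=21))
            s = GrowthSample(well_id="A1", times=s.times, raw=s.raw, corrected=s.raw)
            res = fit_logistic(s)
            sigmas.append(res.sigma)
        assert all(a > b for a, b in zip(sigmas, sigmas[1:]))
        assert sigmas[-1] == pytest.approx(0.0, abs=1e-6)

    def test_time_unit_covariance(self):
        """Refitting with time in minutes scales r by exactly 1/60 and leaves
        K and N0 unchanged, to fit tolerance."""
        hours = noiseless_sample(K=0.7, r=0.9, N0=0.005)
        minutes = GrowthSample(
            well_id="A1", times=hours.times * 60, raw=hours.raw, corrected=hours.raw
        )
        res_h = fit_logistic(hours)
        res_m = fit_logistic(minutes)
        assert res_h.params.r / res_m.params.r == pytest.approx(60.0, rel=1e-6)
        assert res_m.params.K == pytest.approx(res_h.params.K, rel=1e-6)
        assert res_m.params.N0 == pytest.approx(res_h.params.N0, rel=1e-6)

    def test_spearman_rate_vs_doubling_time_is_minus_one(self):
        rng = np.random.default_rng(13)
        rates, tdts = [], []
        for _ in range(20):
            K, r, N0 = rng.uniform(0.3, 1.5), rng.uniform(0.3, 2.5), 0.005
            res = fit_logistic(noiseless_sample(K, r, N0))
            if res.converged:
                rates.append(res.params.r)
                tdts.append(res.t_dt)
        assert exact_spearman(rates, tdts) == -1.0
        rho, _ = spearmanr(rates, tdts)
        assert rho == pytest.approx(-1.0, abs=1e-12)


class TestSummarizeGrowth:
    def test_matches_manual_composition(self):
        s = generate_curve(SyntheticCurveSpec(K=0.6, r=1.0, N0=0.01, noise_sd=0.004, seed=2))
        auto = summarize_growth(s)
        manual = fit_logistic(subtract_min_background(s))
        assert auto.params == manual.params
        assert auto.auc_l == manual.auc_l and auto.auc_e == manual.auc_e

    def test_auc_window_honored(self):
        s = generate_curve(SyntheticCurveSpec(K=0.6, r=1.0, N0=0.01, noise_sd=0.0))
        half = float(s.times[-1]) / 2
        res = summarize_growth(s, t_auc_end=half)
        assert res.auc_l == pytest.approx(
            logistic_auc(res.params, float(s.times[0]), half), rel=1e-14
        )
        corrected = s.raw - s.raw.min()
        assert res.auc_e == pytest.approx(
            empirical_auc(s.times, corrected, half), rel=1e-14
        )

    def test_background_offset_pipeline_recovers_capacity(self):
        spec = SyntheticCurveSpec(K=0.7, r=0.9, N0=0.005, noise_sd=0.0, background=0.09)
        res = summarize_growth(generate_curve(spec))
        assert res.converged
        assert res.params.K == pytest.approx(0.7, rel=0.05)
        assert res.params.r == pytest.approx(0.9, rel=0.05)

    def test_t_auc_end_outside_range_rejected(self):
        s = generate_curve(SyntheticCurveSpec())
        with pytest.raises(InvalidIntervalError):
            summarize_growth(s, t_auc_end=1e6)
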