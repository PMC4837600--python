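"""Fit one well and read off the growth metrics.

Builds a realistic synthetic OD600 trajectory (known ground truth:
K=0.7, r=0.9/h, N0=0.005, media background 0.09, instrument noise
sd 0.005), corrects the background and fits the logistic model.
"""

from growthfit import SyntheticCurveSpec, generate_curve, summarize_growth

spec = SyntheticCurveSpec(
    K=0.7, r=0.9, N0=0.005, noise_sd=0.005, background=0.09, seed=42
)
sample = generate_curve(spec)
result = summarize_growth(sample)  # default: subtract per-well minimum, then fit

p = result.params
print(f"converged      : {result.converged}")
print(f"K (capacity)   : {p.K:.4f}  +/- {result.stderr_K:.4f}  (true 0.7)")
print(f"r (growth rate): {p.r:.4f}  +/- {result.stderr_r:.4f}  (true 0.9 /h)")
print(f"N0 (inoculum)  : {p.N0:.5f} +/- {result.stderr_N0:.5f} (true 0.005)")
print(f"doubling time  : {result.t_dt:.4f} h   (ln 2 / r)")
print(f"t_mid          : {result.t_mid:.4f} h   (curve reaches K/2)")
print(f"logistic AUC   : {result.auc_l:.4f}")
print(f"empirical AUC  : {result.auc_e:.4f}")
print(f"sigma          : {result.sigma:.5f}  (residual SD, OD units)")
# K, r, N0 should land within a few percent of truth; the two AUCs agree
# closely because the trapezoid sum tracks the fitted curve.
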