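# growthfit

Interpretable metrics from microbial growth curves.

Plate readers produce hundreds of absorbance (OD600) time series per
experiment — one growth curve per well.  `growthfit` fits each curve to
the standard logistic equation of population ecology,

```
N(t) = K / (1 + ((K - N0) / N0) * exp(-r t))
```

and reports the quantities microbiologists actually reason about:

| metric | meaning |
|---|---|
| `K` | carrying capacity — the curve's upper asymptote |
| `r` | intrinsic growth rate (per time unit of the input) |
| `N0` | initial population size, `N(0)` |
| `t_dt` | fastest doubling time, `ln 2 / r` |
| `t_mid` | inflection time, where `N = K/2` |
| `auc_l` | area under the fitted logistic curve (closed form) |
| `auc_e` | trapezoid-rule area under the observed readings |
| `sigma` | residual standard error of the fit |

Parameters are estimated by bounded nonlinear least squares
(trust-region reflective, a Levenberg–Marquardt-compatible variant)
from a data-driven starting point.  Media absorbance is removed before
fitting, either by subtracting each well's minimum reading (the default,
no blank well needed) or by subtracting a designated blank-well series.
All outputs inherit the time unit of the input: feed times in minutes
and `r` comes back per minute.

It is aimed at anyone running growth experiments in 96-well plates —
experimental evolution, strain panels, media comparisons — who needs a
per-well summary table rather than raw kinetic traces.

## Worked example

```python
from growthfit import SyntheticCurveSpec, generate_curve, summarize_growth

spec = SyntheticCurveSpec(K=0.7, r=0.9, N0=0.005,
                          noise_sd=0.005, background=0.09, seed=42)
result = summarize_growth(generate_curve(spec))
```

Running `python examples/fit_single_well.py` (which is exactly this)
prints:

```
converged      : True
K (capacity)   : 0.7001  +/- 0.0005  (true 0.7)
r (growth rate): 0.8995  +/- 0.0048  (true 0.9 /h)
N0 (inoculum)  : 0.00507 +/- 0.00013 (true 0.005)
doubling time  : 0.7706 h   (ln 2 / r)
t_mid          : 5.4702 h   (curve reaches K/2)
logistic AUC   : 12.9667
empirical AUC  : 12.9671
sigma          : 0.00431  (residual SD, OD units)
```

The fitted parameters land within a fraction of a percent of the ground
truth despite the 0.09 media offset and realistic instrument noise; the
doubling time is `ln 2 / 0.8995 = 0.77 h`; the two AUC estimates agree
because the trapezoid sum tracks the fitted curve.  The other scripts in
`examples/` fit a whole simulated 96-well plate and explore how the
metrics correlate across wells.

## Command line

```bash
# simulate a plate with known ground truth
growthfit generate plate.csv --wells 96 --k 0.7 --r 0.9 --n0 0.005 \
    --noise-sd 0.005 --background 0.09 --seed 7

# fit every well, write one summary row per well
growthfit fit-plate plate.csv summary.csv

# fit a single two-column (time, reading) file
growthfit fit single.csv
```

Input plates are wide delimited tables: one `time` column
(case-insensitive, configurable via `--time-column`), one column per
well, comma or tab delimited (auto-detected).  Exit codes: 0 when at
least one well converged, 2 when none did, 1 on I/O or parse errors.
Logs go to stderr, data to stdout/files.

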