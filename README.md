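# contrastadapt

A headless simulation and analysis toolkit for **contrast adaptation**
(perceptual fading) matching experiments.

Prolonged exposure to a high-contrast grating desensitizes cortical
neurons tuned to it, so the same physical contrast subsequently *looks*
weaker — and the loss of apparent contrast is larger the lower the test
contrast. The classic way to measure this is a method-of-adjustment
matching task: a reference grating of contrast `c` appears above fixation
and the observer adjusts a second grating below fixation until the two
look identical, before and after adapting to a 0.7-contrast grating in
the upper location. This package implements every component of that
experiment except the human: stimulus synthesis, the logarithmic contrast
slider, balanced trial plans for both protocols, a generative simulated
observer, and the statistical analysis, so the whole pipeline can be run
and tested end-to-end on a machine with no display.

Intended users: vision scientists and instructors who want a reproducible,
scriptable model of this experiment — for power analysis, for validating
analysis code against a known generative truth, or for producing teaching
material.

## The model

Matched contrast is modeled on the natural-log scale as a linear function
of reference contrast with an adaptation-dependent intercept and slope,
plus a per-observer random intercept:

```
ln(match)_ij = β₀ + β₁·ln(c_ij) + [β₂ + β₃·ln(c_ij)]·A_ij + u_i + ε_ij
u_i ~ N(0, σ_id²),   ε_ij ~ N(0, σ_eps²)
```

where `A` indicates the adaptation condition. Veridical matching in the
control condition means β₁ ≈ 1; contrast adaptation shows up as β₃ > 0
(the adaptation line is steeper than +1 on log-log axes, i.e. the apparent
contrast loss grows as `c` falls). The simulated observer generates data
from exactly this law; defaults are the coefficients fitted to the
two-observer replication dataset (β₀ = −0.084, β₁ = 0.982, β₂ = 0.052,
β₃ = 0.443, σ_eps = 0.2875, σ_id = 0.0424).

The analysis layer provides, mirroring the standard reporting of this
experiment:

* per-(observer, condition, level) means/SDs of the raw-scale matches,
* pooled per-condition OLS of ln(match) on ln(c) with full inference
  (SE, t, 95% CI, R², RMSE, F vs constant model),
* the random-intercept LMM above, fit by maximum likelihood with the
  variance ratio λ = σ_id²/σ_eps² profiled out (closed-form GLS at each λ,
  1-D bounded search; the σ_id = 0 boundary is allowed and flagged).

Two slider variants are modeled. The replication slider holds 1000
log-spaced contrasts on [0.01, 1] with a zero entry prepended. The
classroom-exercise slider holds 1000 log-spaced contrasts on [0.05, 1]
and is *cut at a random position on every trial* — the value at the cut
becomes position 0 and earlier values wrap to the end — so an observer
cannot reuse remembered slider positions.

Stimulus images use patch-centered coordinates in degrees of visual angle
(DVA), x rightward and y downward, with normalized luminance in [0, 1]
and no gamma model.

## Worked example

Refit the bundled two-observer per-level summary data (22 control points =
2 observers × 11 levels, 12 adaptation points):

```
$ contrastadapt replicate
== control condition: pooled log-log linear model ==
observations 22  error df 20  RMSE 0.08492  R2 0.995  adj R2 0.994
F vs constant model 3644 (p 4.15e-24)
                    estimate       se   ci_low   ci_high       t          p
Intercept          -0.078148 0.038845 -0.15918 0.0028801 -2.0118   0.057907
log(upperContrast)   0.97189   0.0161  0.93831    1.0055  60.365 4.1483e-24

== adaptation condition: pooled log-log linear model ==
observations 12  error df 10  RMSE 0.1373  R2 0.978  adj R2 0.976
F vs constant model 443.3 (p 1.3e-09)
                    estimate      se   ci_low  ci_high        t         p
Intercept          -0.039958 0.09046 -0.24152   0.1616 -0.44172   0.66809
log(upperContrast)    1.3744 0.06528    1.229   1.5199   21.054   1.298e-09
```

Read: control matching is essentially veridical (slope 0.97, CI includes
1), while the adaptation slope of 1.37 is significantly above 1 — matches
fall increasingly short of the reference as contrast decreases, the
signature of contrast adaptation.

Simulate a full classroom session (6 practice + 60 control + 60 adaptation
trials) and analyze it:

```
$ contrastadapt simulate --seed 7 --out demo.csv        # 126 trial records
$ contrastadapt analyze demo.csv --out-dir report
== control condition (n=6 level means) ==
                    estimate       se   ci_low  ci_high      t          p
Intercept           0.018241 0.086822 -0.22281   0.2593 0.2101    0.84386
log(upperContrast)    1.1038 0.062654  0.92982   1.2777 17.617 6.0974e-05
R2 0.9873  adj R2 0.9841  RMSE 0.0932  F 310.4 (p 6.1e-05)
== adaptation condition (n=6 level means) ==
                    estimate       se   ci_low  ci_high       t         p
Intercept           -0.13734 0.076294 -0.34917  0.07448 -1.8002    0.1462
log(upperContrast)    1.3346 0.055056   1.1818   1.4875  24.241 1.718e-05
```

`report/` receives the per-level summary CSV, the fit report and a log-log
results figure; a JSON manifest (command, config, seed, version) is
written beside every output so any run can be reproduced exactly.

The same machinery is available as a library:

```python
import numpy as np
from contrastadapt import PopulationParams, simulate_replication_experiment, fit_lmm

rng = np.random.default_rng(1)
records = simulate_replication_experiment(PopulationParams(), rng)  # 2 observers, 340 trials
fit = fit_lmm(records)
print(fit.fixed.loc["condition:log_upper", "estimate"])  # ~0.443
```

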