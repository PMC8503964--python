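# Methods

## The experiment being modeled

A two-condition method-of-adjustment contrast matching task. On every
trial a vertical sinusoidal grating (3 cycles/DVA, 3×3 DVA, Gaussian
envelope) appears 3 DVA above a central fixation cross at one of a fixed
set of reference contrasts; the observer adjusts a second grating 3 DVA
below fixation, via a 1000-step logarithmic slider, until the two appear
equal. The *control* condition presents 11 reference contrasts
(geometric steps on [0.02, 0.70]) ten times each, in random order, with a
10-s blank inter-trial pause (110 trials). The *adaptation* condition
presents the upper 6 of those contrasts ten times each (60 trials), after
180 s of initial exposure to a 0.7-contrast grating in the upper location
and with a 10-s 0.7-contrast top-up between trials. A streamlined
classroom variant runs 6 unrecorded practice trials, then 60 control and
60 adaptation trials over the 6 shared levels in one seamless session.

The package executes these protocols headlessly: timing constants are
carried as trial metadata (never slept), and responses come from a
generative observer model.

## Stimulus model

Luminance is normalized to [0, 1] around a mid-gray background Lb = 0.5:

    L(x, y) = Lb · (1 + c · exp(−(x²+y²)/(2σ²)) · sin(2π f x + φ))

with patch-centered coordinates in DVA (x rightward, y downward).
Choices made where the display description is silent:

* **Envelope width** σ = size/6 by default, the common convention for a
  Gaussian mask that fades to near-background at the patch edge (±3σ);
  both σ and the phase φ (default 0) are exposed as parameters, and
  σ = ∞ disables the mask (used when verifying nominal Michelson
  contrast on a dense grid).
* **No gamma / monitor model.** Output is abstract normalized luminance;
  values are clipped to [0, 1] (clipping is inert for Lb = 0.5, c ≤ 1).
* Rendering is deterministic; `michelson_contrast` of an unmasked
  rendering converges to the nominal contrast as pixel density grows
  (the sampled extrema miss the true ones by O((πf/ppd)²)).

## Slider scales

`log_spaced(lo, hi, n)` is the exact geometric sequence
vᵢ = lo·(hi/lo)^(i/(n−1)). The replication slider is
[0] ++ log_spaced(0.01, 1, 1000) (zero lets the match grating be switched
off; it is never rotated). The exercise slider is log_spaced(0.05, 1,
1000); each exercise trial draws a cut position uniformly over all 1000
positions (no distribution was specified; uniform is the natural
maximum-entropy choice) and rotates the list so the cut value sits at
position 0. Quantization of an intended match onto the slider minimizes
|ln v − ln target| — log distance is the natural metric on a geometric
scale. Targets below the smallest positive value clamp to it; a target of
exactly 0 maps to the zero entry when one exists.

The replication slider's per-trial starting position is not modeled (the
simulated observer responds with a contrast, not a trajectory); position 0
is the documented default.

## Observer model

    ln(match) = (β₀ + u) + β₁ ln c + [β₂ + β₃ ln c]·1{adaptation} + ε,
    u ~ N(0, σ_id²), ε ~ N(0, σ_eps²)

Noise is Gaussian on the natural-log scale (lognormal in contrast),
i.e. the generative process mirrors the error structure of the model the
analysis fits. This is an assumption: the matching law describes fitted
population coefficients, not a mechanistic account of any observer, and
no contrast-gain-control front end (e.g. Naka–Rushton) or adaptation
dynamics over the 180-s induction are modeled. Defaults are the
population estimates from the two-observer dataset (β₀ = −0.084,
β₁ = 0.982, β₂ = 0.052, β₃ = 0.443, σ_eps = 0.2875, σ_id = 0.0424), so
that analysis-side recovery targets known values. Intended matches are
clamped into the active slider's positive range before quantization (the
log model cannot produce 0); with σ_eps = 0.2875 the 1.0 ceiling is
occasionally active at the highest reference contrast, a truncation that
real observers face identically on the physical slider.

## Session engine

"Pseudo-random selection with 10 matches per level" is implemented as a
balanced shuffled deck — exact per-level counts, uniformly random order —
rather than independent draws, because the protocol asserts exact
repetition counts. One seeded `numpy` Generator per session drives trial
order, exercise cuts and observer noise, making every run bit-reproducible
from (config, seed). Practice trials use rotated scales exactly like main
exercise trials (they are structurally control trials) and are flagged and
excluded from analysis. Records round-trip through a fixed-schema CSV
(floats serialized with `repr`, so read-after-write is exact); malformed
rows are reported with their line number.

## Statistical analysis

All logarithms are natural. The per-level summary takes means and sample
SDs (n−1) of the **raw-scale** matches and only then log-transforms the
means for the pooled fits (average first, then fit to log data).

**Pooled OLS** (`fit_loglog`) regresses ln(mean match) on ln(reference),
pooling observers within a condition; inference is textbook OLS — SEs
from s² = SSE/(n−2), 95% CIs via Student t(n−2), R², adjusted R²,
RMSE = √(SSE/(n−2)), and the F test against the constant model. The
implementation delegates to `statsmodels.OLS`; the test suite checks it
against an independent normal-equations solve. Slope and R² are invariant
to the log base; the intercept scales by 1/ln(10) under base-10 logs.

**Random-intercept LMM** (`fit_lmm`) fits all trial-level log matches
simultaneously by maximum likelihood (not REML — ML is what the reported
AIC/logLik correspond to, and is exposed as the only mode). With
V = σ_eps²(I + λ ZZ') block compound-symmetric, each group's inverse
correlation is I − λ/(1+λn_g)·J (Woodbury), so for fixed
λ = σ_id²/σ_eps² the GLS fixed effects and the profiled σ_eps² are closed
forms; the deviance is then a smooth 1-D function of λ minimized by
bounded search on ln λ over [1e−9, 150]. The λ = 0 endpoint (pure OLS) is
evaluated explicitly; a boundary optimum is allowed, flagged, and reported
as σ_id = 0 with an undefined (NaN) Wald interval. Numerical choices:

* fixed-effect df = n − k (residual-df convention, k = 4), two-sided
  t-based p values and 95% CIs — no Satterthwaite/Kenward–Roger
  correction, no random slopes;
* variance-component 95% CIs are Wald intervals on the log-SD scale,
  from a central-difference Hessian of the β-profiled deviance;
* AIC = deviance + 2k_total, BIC = deviance + ln(n)·k_total with
  k_total = 6 (4 fixed effects + 2 variance components);
* non-positive matched contrasts (possible on the replication slider's
  zero entry) are excluded from log-scale fits with a warning and a
  recorded count; no multiple-testing correction is applied anywhere.

The statsmodels `MixedLM` implementation of the same model is used in the
test suite as an independent oracle (coefficients agree to ≤1e−6), never
as the fitting path.

**Bundled dataset.** `data/table3_matches.csv` holds the per-level
mean/SD/n of the two replication observers' matches (2×11 control,
2×6 adaptation rows). Refitting it reproduces the published pooled
regressions: control slope 0.9719 / R² 0.994, adaptation slope 1.3744 /
R² 0.978, agreeing with the printed coefficients to within what 4-decimal
rounding of the level means permits (~0.001 on slopes).

## What the simulations do and do not show

The synthetic observer reproduces the design exactly — sample sizes
(2 observers × (110 + 60) trials), the published effect sizes, and
homoscedastic lognormal trial noise at the pooled residual SD. Real
matching data differ in ways the generator ignores: trial-level noise is
closer to Weber-like (roughly contrast-proportional SD, so the *pooled*
log-scale SD understates low-contrast noise and overstates high-contrast
noise), there are sequential effects, lapses, and drift of the adapted
state over a session. Passing recovery tests therefore certifies the
*analysis pipeline* (unbiasedness and CI calibration under the assumed
error structure), not robustness to those departures.

Problem sizes used in the checks: the parameter-recovery study runs 200
replicate experiments at the full published design (340 trials each),
chosen to pin the Monte-Carlo SEM of the mean interaction estimate near
0.003 — an order of magnitude below the effect — while the whole study
completes in a few seconds.

## Known limitations

* No interactive presentation: frame timing, mouse/keyboard handling and
  monitor calibration are out of scope by design.
* The LMM supports a single random intercept per observer only.
* Wald variance CIs degrade near the σ_id = 0 boundary (reported NaN at
  it); profile-likelihood intervals are not implemented.
* With only two observers, σ_id is weakly identified and its ML estimate
  frequently sits at the boundary; fixed-effect inference is unaffected
  in the balanced designs used here.
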