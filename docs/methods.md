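# Methods

## Scope and model

The package estimates per-window energy expenditure (EE, kcal/min) from
four raw chest/abdomen distance signals sampled at 15 Hz, using a temporal
convolutional network (TCN), and evaluates agreement against
indirect-calorimetry-style references. EE is tied to oxygen uptake by the
caloric equivalent of oxygen, EE = V̇O₂ (L/min) × 4.825 kcal/L, which is
exact for the synthetic ground truth and therefore makes EE and V̇O₂
interchangeable regression targets up to units.

All empirical statements below (threshold recovery, held-out R², coverage
numbers) are the quantities the test suite and `scripts/acceptance.py`
compute; nothing is quoted from elsewhere.

## Synthetic graded-exercise generator

The generator is first-class, tested code, not a fixture. It emulates a
maximal graded test (MGT): 6 min sitting or standing, 2 min rest on the
ergometer, then a continuous ramp — 20 W·min⁻¹ for subjects aged ≤ 12 y,
30 W·min⁻¹ otherwise — ending in a V̇O₂ plateau at V̇O₂max held for
`plateau_s` (default 45 s).

**Subjects.** Age, height, body mass and V̇O₂max are truncated-normal draws
from per-group cohort means/SDs (adults ~28 y, 70.7 kg, 3.16 L/min;
post-pubertal ~14.8 y, 56.6 kg, 3.29 L/min; pubertal ~11.7 y, 41.7 kg,
1.99 L/min); BMI is computed, not drawn.

**Gas exchange.** V̇O₂ demand is resting metabolism (`vo2_rest`, default
3.5 mL/min/kg — the conventional 1-MET value) plus a linear on-power cost
(`vo2_per_watt`, default 10.3 mL/min/W — the standard cycle-ergometry
economy), capped at V̇O₂max. Ventilation follows a piecewise
ventilatory-equivalents model parameterized by the fraction f = V̇O₂/V̇O₂max:
V̇E/V̇O₂ is flat (24) below `th1_frac` (0.55), rises with slope 20 per unit f
between the thresholds and 45 above `th2_frac` (0.80); V̇E/V̇CO₂ is flat at
24/RER_rest (RER_rest 0.85) until `th2_frac` and then rises with slope 18.
This construction puts exactly two breakpoints on the ramp (the two
ventilatory thresholds) and makes RER = (V̇E/V̇CO₂)⁻¹·(V̇E/V̇O₂) climb through
1.1 between V_Th2 and exhaustion — the canonical respiratory-equivalents
picture. Breath durations derive from tidal volume: VT grows from ~9 % to
60 % (`vt_fraction_max`) of a height-scaled vital capacity as ventilation
rises, and duration = 60·VT/V̇E (clipped to 1.3–5 s), so breathing deepens
first, then quickens (~4.5 s at rest to ~1.6 s at maximum). Per-breath
multiplicative gaussian noise (`noise_sd_gas`, default 3 %) perturbs V̇O₂
and V̇E independently; EE is always computed exactly from the (noisy) V̇O₂.

**Distance traces.** Each breath contributes a raised-cosine volume
excursion of amplitude VT = V̇E·duration/60. The volume is split across the
four channels by per-subject fractions (defaults 0.45/0.45/0.07/0.03 for
RC/AB/CW/SP) and converted to centimetres by per-subject gains (L/cm,
defaults 0.40/0.50/0.15/0.10 with 10 % between-subject spread), so the
gain-weighted sum of channel excursions reconstructs VT exactly — a
four-channel extension of the Konno–Mead two-compartment chest-wall model.
Channels sit on height-scaled baselines; additive gaussian sensor noise
(`noise_sd_distance`, default 0.05 cm) is applied per sample. The trace is
evaluated analytically on the exact 15 Hz grid, so no resampling error
enters.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: chaotic/irregular ventilatory dynamics, posture
and movement artifacts, sensor drift, thoraco-abdominal asynchrony,
cardiogenic oscillations, and the breath-shape variety of real subjects.
The signal-to-EE mapping is cleaner than reality, especially at rest, so
synthetic-recovery R² values are optimistic relative to field performance.

## Windowing and targets

Windows are 5 s (75 samples/channel) at 80 % overlap (1 s step), anchored
at t = 0 of each recording; the count obeys floor((T−5)/1)+1. A 5 s window
covers at least one breathing cycle at any intensity. Targets are
time-weighted means of the breath values overlapping the window (unbiased
under variable breath durations); windows overlapped by no breath are
dropped and counted. Signals are z-scored per channel with statistics from
the training split only; an exact inverse transform is kept, and
normalization can be disabled.

## Threshold detection

Human readers locate the thresholds visually; the package substitutes a
reproducible surrogate. V_Th2 is the breakpoint of a two-segment continuous
piecewise-linear (hinge) least-squares fit to V̇E/V̇CO₂ over the ramp; V_Th1
is the hinge of V̇E/V̇O₂ restricted to times before V_Th2 (beyond V_Th2 the
oxygen equivalent steepens again and would bias a single hinge). A
breakpoint is accepted only if the hinge improves the straight-line SSE by
at least 20 % and the post-break slope exceeds the pre-break slope;
V̇E/V̇CO₂ must be stable before its own break (|slope| below 10 % of the
post-V_Th1 V̇E/V̇O₂ slope). Otherwise the series is declared indeterminate.
On noiseless simulations the detector recovers both thresholds within 15 s
of the generator's breakpoints for 10/10 seeded subjects (the V_Th2
estimate is biased ~10 s late by the terminal plateau); under default noise
the median error stays within 30 s. Intensity labels follow window
midpoints with left-closed upper ranges (a midpoint exactly at a threshold
joins the higher intensity).

## TCN regressor

Implemented in numpy with hand-written forward/backward passes (im2col over
kernel taps feeding BLAS matmuls, float32), because the network itself is
the package's core and its gradients are directly testable (the suite
checks them against finite differences). Architecture: dilations
2⁰ … 2ⁿ⁻¹, one causal convolution per dilation level with ReLU, grouped
into residual blocks — with an odd number of levels the earlier block takes
the extra one (5 levels → 3 + 2) — identity skip, or 1 × 1 convolution
where channel counts differ, ReLU after the sum; a dense linear head reads
the features at the final time step. Receptive field
RF = 1 + (k−1)(2ⁿ−1); the default (k = 3, n = 5) gives 63 samples ≈ 4.2 s,
inside the 75-sample window. The suite cross-checks the formula with an
independent perturbation oracle (count of input positions that influence
the output of a randomly initialized network).

Training: Adam (β₁ 0.9, β₂ 0.999) on mean squared error; defaults lr 0.001,
batch 1024, 80 epochs; targets are standardized internally and
de-standardized (and clipped at zero) at prediction. The best
validation-epoch weights are retained. Initialization is He-scaled and
seeded; two runs with the same seed are bit-identical. K-fold
cross-validation (default 5) re-trains from scratch per fold and is exposed
as `cross_validate` / `run_cv=True`; the scripted study leaves it off by
default to keep the one-command reproduction light.

Splitting is 55/20/25 train/validation/test. The default `sample` mode
shuffles windows individually; since neighbouring windows share 80 % of
their samples this leaks local signal structure across splits — it is kept
as the default because it reproduces the reference protocol, and a
`subject` mode (no subject spans two splits) is provided for honest
generalization. Validation counts use round(0.2·n), e.g. 1590 of 7950.

## Evaluation statistics

R² is the regression coefficient of determination 1 − SS_res/SS_tot (not a
squared correlation). Bland–Altman limits default to bias ± 1.96 SD; a
multiplier of 2 reproduces the ±2 SD plotting convention. Per-intensity
comparisons run a KS normality check on the standardized paired
differences, log-transform both series when normality fails and all values
are positive (falling back, with a logged warning, otherwise), and report
paired t-test p-values with NS/*/**/*** tiers at 0.05/0.01/0.001. The
sample-size helper is n = ceil(z²p(1−p)/m²) (457 at z = 1.96, p = 0.05,
m = 0.02), and the windows-per-subject bookkeeping is 120 × subjects.

A known limitation: with multiplicative gas noise the per-window target
noise scales with EE, so prediction–reference differences over a maximal
test (EE ~1–16 kcal/min) form a heteroscedastic scale mixture with excess
kurtosis. Coverage of the ±1.96 SD band then sits slightly below the
gaussian 95 % (~93–95 % in the shipped configuration) no matter how well
the model fits — an intrinsic property of proportional-error agreement
data, visible in the Bland–Altman tests.

## Problem sizes

The scripted study defaults to 9/8/6 subjects for groups A/PP/P — one
model per group and target, matching the per-group reporting — and the
recovery experiment in the acceptance script uses 8 subjects and 30 epochs
(~10⁴ windows, a few minutes on one CPU); both are configurable. Synthetic
window totals depend on simulated ramp durations and are reported, never
forced to match any external count.
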