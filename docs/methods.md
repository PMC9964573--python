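# Methods

This package predicts mass-normalized oxygen uptake (V̇O2, mL/min/kg)
during walking and running from per-step motion metrics and, optionally,
heart rate, using a many-to-one LSTM regressor. Because the field
recordings such models are built on are not publicly distributable, the
package also contains a synthetic cardiorespiratory/gait generator that
reproduces the statistical structure the analysis relies on; every stage
of the pipeline is tested against that generator's ground truth.

## The prediction problem

A torso-worn INS/GPS device yields speed and vertical displacement at
hundreds of Hz; a portable spirometer yields breath-by-breath V̇O2 at
0.2 Hz; a heart-rate monitor yields ~1 Hz HR. After synchronization and
step segmentation, each step *k* carries up to five features

* v̄ₖ — mean speed over the step (m/s),
* Δvₖ — within-step peak-to-peak speed (m/s),
* Tₖ — step duration (s),
* Δzₖ — within-step peak-to-peak vertical displacement (m),
* HRₖ — heart rate at the step (bpm),

and the model maps a window of L = 50 consecutive steps (≈ 20–25 s of
locomotion) to the V̇O2 at the window's last step:

    ŷₖ = f_θ(x_{k−L+1}, …, x_k),   x ∈ [0,1]^F after min–max scaling.

The regressor is a single LSTM layer with H = 150 hidden units followed
by a dense layer with one output. Parameter total per LSTM layer is
4H(F + H + 1) (one bias vector per layer, as in MATLAB's `lstmLayer`),
plus H + 1 for the head; with F = 4 this gives 93,151 trainable
parameters. Training minimizes mean squared error with Adam
(learning rate 0.005) on shuffled minibatches of 64; inputs are scaled
to [0,1] with bounds fitted on the training split only (test values are
clipped), and targets stay in physical units. The LSTM, backpropagation
through time and Adam are implemented directly on NumPy
(`vo2lstm.lstm`); gradients are verified against central finite
differences in the test suite, and the default epoch budget of 8000
mirrors field practice while a few hundred epochs suffice at the
synthetic benchmark's size.

## Synthetic data generator

`vo2lstm.synthetic` emulates a track test: 3-min stages at two walking
and two running speeds (1.3–3.5 m/s), separated by standing rests, ~20 min
in total, starting from rest.

**Metabolic model.** Steady-state V̇O2 is linear in speed with
gait-specific slope, in the spirit of the ACSM metabolic equations:
vo2_rest + 6.0·v when walking, vo2_rest + 12.0·v when running (slopes
configurable). The latent V̇O2 follows first-order kinetics
dV/dt = (V_ss − V)/τ with τ_on = 35 s when rising and τ_off = 45 s when
recovering — typical for moderate-intensity exercise, and fast enough
that a 3-min stage reaches steady state. Heart rate relaxes toward the
rate implied by the fractional V̇O2 reserve with τ_HR = 25 s. The
integrator uses the exact exponential update for piecewise-constant
forcing, so on constant-speed segments the latent trace equals the
closed-form solution to machine precision (an explicit Euler scheme was
considered and rejected because its O(dt/τ) bias would dominate the
analytic-oracle tests).

**Gait model.** Step frequency is linear in speed
(1.4 + 0.45·v steps/s by default; ~0.36 s steps at 3 m/s), with 2%
multiplicative duration jitter. Within a step the vertical position
completes one oscillation (peak-to-peak 0.05 m walking, 0.09 m running)
and speed oscillates around the stage pace. Actual pace wanders around
the target as an Ornstein–Uhlenbeck process (SD 0.1 m/s, 15 s
correlation time), emulating subjective pacing on an open track.

**Gait–metabolic coupling (gait settling).** Gait is not constant within
a stage: while the oxygen deficit
d(t) = (V_ss − V̇O2(t))/(V_ss − V̇O2_rest) decays after a stage onset,
the runner has not yet settled into the preferred gait — cadence sits
5% lower and vertical oscillation 10% higher per unit deficit, both
relaxing with the on-transient. This mirrors the settling of step
parameters observed over the first minute of a constant-pace stage and
couples the step metrics to the metabolic state. It matters
structurally: under first-order kinetics with strictly constant gait, a
50-step window deep inside a stage would carry no information about
elapsed time since the stage began, leaving the within-stage transient
unresolvable from motion alone (only heart rate, itself lagging V̇O2,
could resolve it). With the coupling, step duration and vertical
oscillation encode the transient state, which is exactly why they add
predictive value beyond speed even though none of them predicts V̇O2
well alone.

**Measurement noise.** Spirometer noise is Gaussian with SD 125 mL/min
divided by body mass (the published accuracy of the Oxycon Mobile
class of devices), applied to 0.2 Hz samples; HR noise SD is 2 bpm at
1 Hz; speed noise SD is 0.05 m/s (the stated accuracy of the INS/GPS
speed output); vertical-position error is modelled as a slow drift
(SD 5 mm, ~2 s correlation) so that per-step displacement errors are of
order 0.01 m without producing spurious oscillation peaks at rest. The
default motion rate is 100 Hz — far above the ~6 Hz needed for the
per-step statistics; the 400 Hz of the real device adds nothing at this
level of modelling and would only slow tests.

**Synchronization artifacts.** Each stream's clock can be offset by up
to ±30 s; a two-footed jump leaves a sharp (≈5 g) spike in vertical
acceleration and bookmark markers (with 0.04 s timing jitter, the
precision of a manual event mark) in the V̇O2 and HR streams. Subjects
are drawn with body mass ~ Normal(78.3, 13.0) kg truncated to
[45, 120] kg.

**What the generator does not emulate** — and hence what passing tests
do not show about field data: day-to-day physiological variability,
temperature/humidity effects, slow V̇O2 component and drift at heavy
intensities, HR artifacts (ectopy, strap dropouts), GPS multipath, gait
asymmetry, and inter-subject transfer. Within-subject agreement numbers
on synthetic data say nothing about generalization across people; the
model is explicitly per-subject.

## Preprocessing choices

* **Bookmark alignment:** the jump time is the global maximum of
  |vertical acceleration| within the first 60 s (minimum amplitude
  20 m/s²); all streams are shifted so their bookmarks coincide at t = 0.
  On synthetic data the residual misalignment is bounded by the marker
  jitter, well under the 0.2 s the analysis tolerates — V̇O2 and HR
  change on time scales of tens of seconds.
* **Savitzky–Golay smoothing:** polynomial order 3, window 11 samples
  (55 s at 0.2 Hz), three passes. A frame length of 1 sometimes quoted
  for this class of processing is not a valid Savitzky–Golay
  configuration (the window must be odd and exceed the order), so the
  smallest conventional window giving visible smoothing at 0.2 Hz is
  used; both order and window are config fields. Edges refit the
  polynomial on truncated windows, preserving length and timestamps.
* **Outlier removal:** samples deviating from a 5-point rolling median
  by more than 5 robust SDs (1.4826 × MAD) are replaced by linear
  interpolation; replacements are logged. With a zero MAD (constant
  signal) any deviation counts as an outlier.
* **Step targets:** the smoothed V̇O2 is interpolated linearly at each
  step's **end** time (anchor configurable: start/mid/end — the natural
  reading of "the V̇O2 a window predicts" is the value when its last
  step completes). Interpolation never extrapolates; out-of-span steps
  are dropped and logged.

## Splits, evaluation and the leakage caveat

The field protocol shuffles all windows and splits 80/20. Adjacent
windows share 49 of their 50 steps, so the shuffled split leaks heavily
between train and test; agreement measured under it is best read as
within-session interpolation accuracy. The `blocked` split mode holds
out a contiguous tail per subject with a guard gap of L − 1 windows
(zero step sharing) and gives the honest, harder number; the shuffled
mode remains the default because it is the protocol the headline
numbers are defined under.

Agreement is summarized Bland–Altman style on residuals defined as
**predicted − measured** (a negative bias means underprediction):
bias = mean residual, residual SD with n − 1, 95% limits of agreement
= 2 × SD exactly (not 1.96), plus residual RMSE. Pooling across
subjects is simple concatenation at fixed pairing.

## Numerical and design notes

* Training is float32 throughout; runs are bit-reproducible under a
  fixed seed on a fixed NumPy/BLAS build. Weight init: Glorot-uniform
  input weights, orthogonal recurrent blocks, zero biases except a unit
  forget-gate bias.
* A constant feature makes min–max scaling degenerate and raises an
  error naming the feature rather than silently emitting NaN.
* Zero-variance features yield NaN (undefined) correlations, never 0.
* The synthetic benchmark used by the expensive end-to-end test is one
  subject under the default protocol (~1,800 steps, ~1,400 training
  windows), H = 150, 300 epochs — large enough for field-grade
  agreement on synthetic data while keeping the suite inside a routine
  CI budget.
* With first-order kinetics, a motion-only window deep inside a
  constant-speed stage carries no information about elapsed time since
  the stage began, so part of the on-transient is unresolvable from
  motion alone; heart rate, lagging V̇O2 itself, supplies exactly that
  state. This is the mechanistic reason the motion+HR model should not
  be worse than motion-only, and it holds on the synthetic benchmark.
* Known limitations: no clock-drift (rate) correction between streams,
  only a constant offset; no repeated-measures correction in pooled
  limits of agreement; single-sensor peak-picking segmentation rather
  than a full navigation-grade step detector; per-subject models only.
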