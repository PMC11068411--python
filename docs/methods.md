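# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind `pupilsdt`, and what the synthetic-data tests do
and do not establish about recorded data.

## Signal-detection analysis

Session-level measures use raw rates; the log-linear correction
(hits + 0.5, false alarms + 0.5, each stimulus count + 1) is applied
automatically when a rate is exactly 0 or 1, and *always* in binned and
tertile analyses, where small cells make extreme rates routine. Mixing
corrected and uncorrected estimators inside one binned analysis would make
bins incomparable, hence the uniform rule; a flag restores raw rates where
both counts permit.

The first 20 trials of every session are excluded before any statistic
(camera-adjustment period). All paradigm-level numbers are unweighted
means of per-session values; pooling trials across sessions is a different
estimator (nonlinear quantile transform) and is deliberately not used.
Reaction times are defined only on responded (hit/false-alarm) trials; an
absent value stays absent rather than becoming zero.

The criterion slope across sensory environments is the least-squares slope
of c against the ordinal paradigm index (1, 2, 3 for Go fractions 0.8,
0.5, 0.2), which for three paradigms reduces to (c₃ − c₁)/2. The ordinal
axis, rather than the Go fraction itself, is what makes the optimal-slope
value ≈ 1.14 reproducible from the per-paradigm optima.

## Pupil preprocessing

Fixed order: blink interpolation → zero-phase low-pass → per-session
Z-score. Reversing filtering and Z-scoring changes the result only by a
scale factor, but interpolation must precede filtering so blink transients
do not ring; the order is regression-locked in the tests. Details:

- Blink gaps are linearly bridged between nearest good samples; leading
  and trailing gaps hold the nearest value. The mask is preserved so that
  trials whose baseline or dilation window is more than 50% interpolated
  (configurable) yield absent features.
- The low-pass filter is a digital 4th-order Butterworth at 3.5 Hz
  (fs = 20 Hz) applied forward and backward (`filtfilt`), i.e. the
  squared magnitude response and zero phase, with 1 s of reflected
  padding against edge transients. At 1 Hz the attenuation matches the
  analog form 1/(1 + (f/3.5)⁸) to three figures; at 5 Hz (a quarter of
  the sample rate) bilinear frequency warping makes the *designed*
  filter's |H|² ≈ 0.0195 rather than the analog 0.054, and the package's
  tests assert the designed response.
- Feature windows are sample-aligned: baseline = mean of the 10 samples
  in [onset − 0.5 s, onset), onset sample excluded; dilation = mean of
  the 101 samples in [onset, onset + 5 s], endpoint included, minus the
  baseline.
- Normalized baselines are min-max per session, so 20-bin and tertile
  analyses are comparable across sessions. Tertile boundaries follow the
  literal rule low < 0.33, 0.33 ≤ medium ≤ 0.66, high > 0.66 (ties to
  medium); b = 1.0 falls in bin 20 of 20.

## Reward-rate optimization

The observer draws evidence from N(0.52, 1) on S+ trials (0.52 is the mean
perceptual sensitivity across the three paradigms) and N(0, 1) on S−
trials, licking when the evidence exceeds the decision criterion. Trial
durations (seconds): hit = U(1, 3.5) + mean RT + 6; miss and correct
rejection = U(1, 3.5) + 1.3 + 6; false alarm = U(1, 3.5) + mean RT + 10 +
6. Only hits pay (60 µL). Defaults: per-paradigm mean RTs 0.4838, 0.594,
0.702 s (the observed grand means, overridable), grid −4 to 1 in 0.05
steps, 15,000 trials per criterion, 20 repeats. The onset tone and
stimulus duration are not added to the simulated durations; the recipe
uses exactly the components listed above.

Within one repeat, a single set of 15,000 stimulus/evidence/wait draws is
evaluated at every grid criterion (common random numbers). Each
per-criterion estimate is unbiased and still uses 15,000 trials; sharing
the draws makes differences between nearby criteria nearly noise-free,
which is what keeps the argmax of this curve meaningful. With independent
draws per criterion the per-repeat argmax has a standard deviation of
0.6–0.9 criterion units — the optimum would be mostly noise.

The closed form behind `analytic_reward_rate` is the renewal-reward
expectation: with h = Φ(0.52 − c) and f = Φ(−c),

    rate(c) = p·h·V / { p[h·d_hit + (1−h)·d_quiet]
                        + (1−p)[f·d_fa + (1−f)·d_quiet] }

with the mean durations above (wait = 2.25 s). Its argmax over the default
grid is −3.25, −1.90, −1.30 for p = 0.8, 0.5, 0.2.

**Flatness caveat.** The curve is extremely flat on its liberal side: for
p = 0.8 the rate changes by < 0.005 µL/s between c = −4 and c = −2.2.
Monte-Carlo argmaxes therefore wander over this plateau even with common
random numbers; across seeds, the 20-repeat mean optimum spans roughly
−3.1 to −2.8 (p = 0.8), −2.0 to −1.9 (p = 0.5) and −1.4 to −1.25
(p = 0.2), with the implied cross-paradigm slope near 0.85. Any downstream
comparison of these optima should treat ±0.1–0.3 criterion units as within
the method's intrinsic uncertainty. The lower grid bound of −4 is itself a
choice forced by the plateau: an unbounded grid makes the argmax
ill-conditioned for Go-rich paradigms.

Argmax ties resolve to the most negative criterion (deterministic and
conservative).

## Drift-diffusion model

Evidence accumulates from z·a toward boundaries {0, a} with drift v₊ (S+)
or v₋ (S−) and unit diffusion; upper-boundary crossing at time τ produces
a lick at τ + t0. Variants: M1 (z = 0.5, v₋ = −v₊; 3 free parameters), M2
(z free; 4), M3 (v₋ free; 4), M4 (both free; 5).

Because withheld responses carry no reaction time, licks and non-licks are
coded as: lick = upper-boundary crossing with rt ≤ deadline (1.3 s);
withhold = everything else (lower absorption *or* censoring at the
deadline). The withhold likelihood is therefore 1 − P(upper crossing
before deadline − t0), the only self-consistent censored mixture given the
observables.

Numerics: the first-passage density uses the dual series expansion for the
Wiener process (small-time and large-time forms), selecting per evaluation
point the form needing fewer terms at a 1e−10 truncation error; the upper
boundary follows from the reflection (z, v) → (1 − z, −v). Crossing
probabilities integrate the density with 96-point Gauss–Legendre on a
square-root time axis (resolving the sharp early rise). Fitting is
multi-start L-BFGS-B within bounds (a ∈ [0.3, 5], z ∈ [0.05, 0.95],
|v| ≤ 8, t0 ∈ [0.01, min(0.95·min rt, deadline − 0.05)]); reaction times
at or below t0 hit a likelihood floor (1e−300) with a warning rather than
an exception, so the optimizer can leave bad regions. Forward simulation
is Euler–Maruyama (dt = 1 ms by default, 0.1 ms in oracle tests; the
boundary-overshoot bias of Euler schemes scales with √dt and is covered by
the test tolerances). Model ranking uses AIC (BIC alongside); hierarchical
group/animal structure and DIC are out of scope by design — fits are
pooled or per-session maximum likelihood.

## Synthetic-session generator

The generator's defaults are the study conditions: three Go fractions
(0.8/0.5/0.2), 270 trials per session (260 sessions × 270 ≈ the recorded
70,516 trials), the timing constants of the task (0.3 s onset tone,
uniform 1–3.5 s delay, 1.3 s response window, 10 s timeout, 6 s ITI,
1–2.5 s impulsive-lick penalty delay, 60 µL reward), and per-paradigm
observers set to the observed grand means (d' = 0.536/0.510/0.518,
c = −1.139/−0.483/0.045, impulsive rates 0.174/0.134/0.062, lognormal RT
medians 0.4838/0.594/0.702 s with shape σ = 0.35, truncated by demotion at
the 1.3 s window).

Conventions chosen where the design was open:

- **Observer convention.** Evidence is N(±d'/2, 1) with lick iff
  evidence > c_trial. Centering the distributions makes the generating
  `criterion_base` and `d_prime` exactly the quantities the
  signal-detection analysis recovers, so parameter-recovery tests are
  exact up to the demotion factor below. (An equivalent convention puts
  S− at 0 and S+ at d'; its threshold then differs from the SDT criterion
  by d'/2, which would make "recovery" systematically off by 0.26.)
- **Deadline demotion.** Lick latencies are drawn once; draws beyond the
  response window demote the trial to miss/correct rejection, exactly as
  a too-slow lick would. Both response probabilities are thereby
  multiplied by q = P(RT ≤ 1.3) ≈ 0.988 at the default lognormal, and the
  recovery oracles use the demotion-corrected rates.
- **Arousal coupling.** c_trial = criterion_base + g₁(b − 0.5) +
  g₂(b − 0.5)², with b the trial's min-max-normalized baseline; defaults
  g₁ = g₂ = 0. The coupling exists to make the tertile analysis testable:
  per-paradigm gains that decrease across paradigms produce a larger
  criterion slope in the low tertile, the pattern the conditioned
  analysis must recover.
- **Baseline-before-outcome ordering.** Trial baselines are drawn first
  as a stationary AR(1) sequence across trials (OU time constant 30 s,
  unit stationary SD, decay set by the expected ~9.9 s trial spacing);
  outcomes and hence outcome-dependent event times follow; the continuous
  20 Hz trace is then pinned to those anchors at the realized onsets.
  This breaks the circularity between arousal-dependent outcomes and
  outcome-dependent timing.
- **Impulsive licks** occur with the paradigm's observed probability and
  add a single penalty delay re-draw (the real task can re-delay
  indefinitely, but trained animals rarely trigger more than one, and a
  single re-draw reproduces the timing statistics without an unbounded
  loop).
- **Pupil trace** = anchored baseline + per-trial dilation kernel
  (t/t_p)·exp(1 − t/t_p) peaking at t_p = 1.2 s, scaled by outcome (peak
  amplitudes 0.156/0.096/0.07/0.0095 for hit/FA/miss/CR — the observed
  ordering), + white noise (SD 0.1) + Poisson blinks (2/min, 0.3 s)
  marked with a −999 sentinel and a mask channel.

What the generator does *not* emulate: within-session nonstationarity
(fatigue, satiation, learning), luminance effects, eyelid/saccade
artifacts beyond blinks, animal-level heterogeneity, and any dependence of
reaction times on arousal. Passing recovery tests therefore show that the
analysis code is correct under the stated generative assumptions, not that
those assumptions hold in recorded data.

## Problem sizes in the test suite

Unit tests run reduced problem sizes (thousands of trials, single
replicates); the acceptance-style tests run the full stated conditions:
15,000 trials × 20 repeats × 101 grid criteria per paradigm for the
reward-rate optima, 100 sessions for signal-detection recovery, 2,000
trials × 20 replicates for drift-diffusion parameter recovery and 5,000 ×
20 for model recovery, and 50,000 walks at dt = 0.1 ms for the
density-versus-simulation oracle. The whole suite completes in a few
minutes on one CPU.

## Known limitations

- The reward-rate optimum for Go-rich paradigms is intrinsically
  ill-determined (plateau); report it only together with its repeat SE.
- The per-paradigm grand means used as generator defaults are mutually
  inconsistent in a strict sense (session-mean d'/criterion are not the
  transforms of grand-mean rates, because the quantile map is nonlinear);
  the generator is parameterized by d'/c, so its emitted rates differ
  slightly from the observed grand-mean rates.
- d' estimates from sessions with few S− (or few S+) trials carry the
  usual small-sample quantile-transform bias; the package reports what
  the estimator gives and does not attempt bias correction.
- The drift-diffusion likelihood omits inter-trial variability parameters
  (sv, sz, st0); with deadline censoring and no-RT withholds they are
  weakly identified and were not part of the four-variant comparison.
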