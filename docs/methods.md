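# Methods

This note documents the models, procedures, numerical conventions, and
design choices behind partkit, and what the simulated-observer tests do
and do not establish about real listeners.

## Adaptive procedure

Two-cue 2AFC trials present four intervals (standard, A, B, standard)
with 250-ms inter-stimulus intervals; the target occupies interval 2 or 3
with equal probability.  Difficulty is adapted by a two-stage
2-down/1-up transformed staircase: two consecutive correct responses move
the adaptive parameter one step toward harder, any error moves it one
larger step toward easier.  The run counter resets after every movement.
Stage 1 uses large steps until three reversals have occurred; stage 2
uses steps 1/5 that size (in the adaptation domain) and ends after six
further reversals.  The threshold estimate is the geometric mean of the
six stage-2 reversal values in native units.

Steps are defined in the adaptation domain of each task: multiplicative
factors for exponentially adapting parameters (gap duration, FM depth —
stage-1 factor 2^(1/2), stage-2 factor 2^(1/10)), additive dB steps for
linear ones (modulation depth 0.5/0.1 dB, masker level 6/1.2 dB).  The
up/down asymmetry is likewise applied in that domain: a 2:1 ratio means
the up factor is the square of the down factor on exponential tracks and
twice the dB step on linear ones.  Only this reading makes the
drift-balance equilibrium come out at the published operating points.

**Convergence target.** At equilibrium the probability flow up and down
must cancel.  A trial produces a down step with probability
p²/(1+p) (stationary run-counter analysis) and an up step with
probability 1−p; with step-size ratio r the balance point solves
p² = r(1−p²), i.e.

    p* = (r / (1 + r))^(1/n)   (n-down/1-up)

giving 81.65% for n=2, r=2 (printed as 81.7), 77.46% for n=2, r=1.5
(printed 77.5), and 79.37% for n=3, r=1 (printed 79.4).

**Reversal conventions.** A reversal is counted at the trial where the
movement direction flips; the logged value is the parameter value before
that trial's step.  The first movement is not a reversal.  Steps clamped
at the track bounds count toward direction state, but identical
consecutive clamped values log at most one reversal.  At the stage
boundary, reversal bookkeeping (including the switch to stage 2) happens
*before* the step size for that trial is chosen — the trial producing the
third stage-1 reversal already moves by the stage-2 step, as in the
step-array indexing of common staircase toolboxes.  This choice matters:
sizing the boundary step by the old stage hands the track to stage 2 a
full stage-1 up-step above its operating point, and because stage-2 steps
are small the six reversals are then collected during a long biased
relaxation — simulations with that convention settle around 85–88%
correct instead of the analytic 81.7%.  With bookkeeping-first, 500
simulated tracks under the battery's geometry converge to within one
percentage point of the analytic target, and long tracks (last 6 of 60
reversals) sit on it almost exactly.

**Masker-level tracks.** The tone-in-noise tests adapt the masker level
upward after correct responses (harder) within 25–90 dB SPL.  The engine
treats this as the same rule with the parameter axis inverted
(`increase_on_correct`); the equilibrium analysis is unchanged.

**Progressive tracking.** The speech tests use a fixed 20-trial schedule:
target fixed at 65 dB SPL, maskers rising 55→73 dB SPL in 2-dB steps
every two trials — two trials at each of ten target-to-masker ratios from
+10 to −8 dB.  The threshold is 10 − (number correct) dB, spanning +10
(none correct) to −10 (all correct), roughly the 50% point of the
underlying psychometric function.  Spatial release from masking is the
colocated minus the separated threshold, in [−20, +20] dB.

## Stimuli

All stimuli are stereo at 44.1 kHz, levels set through a calibration map
that assigns 0 dBFS RMS to 100 dB SPL (configurable); level-setting is
pure scaling and clipping is a hard error rather than saturation.
Gating ramps are raised-cosine: full Hann envelopes on the 4-ms gap
bursts (the stimulus is too short for flat-topped gating), 10-ms on/off
ramps elsewhere.  The gap is defined between the 0%-envelope offset of
burst 1 and onset of burst 2, and the 80-dB-SPL target applies to the
burst samples so that burst amplitude is gap-invariant.

FM stimuli draw a fresh carrier uniformly from 460–550 Hz on every call —
including every standard interval — so the task cannot be solved by pitch
matching.  The modulator starting phase is drawn uniformly to remove
onset cues.  The dichotic variant sign-inverts the modulator at the right
ear, which sweeps the interaural phase difference sinusoidally at the
modulation rate with amplitude 2·depth/rate radians.

Modulated-noise carriers are built in the frequency domain from every FFT
component in 0.4–8 kHz (the maximum the sampling rate and duration
allow), with Rayleigh amplitudes and uniform phases.  The modulation gain
surface

    G(t, x) = depth · sin(2π(rate·t ± density·x) + φ)   [dB],
    x = log2(f / 400 Hz)

is applied per component, making the mid-to-peak dB depth exact by
construction.  Pure TM reduces to a time-domain envelope, pure SM to a
static spectral gain; the joint (STM) case is evaluated chunked over
time.  The ± sign sets the ripple drift direction; "up" is the
spectro-temporal mirror (x → −x) of "down" at the same seed.

Notched-noise maskers place 10 000 sinusoids log-uniformly over
1.2–2.8 kHz (no-notch) or over 0.8–1.6 ∪ 2.4–3.2 kHz (notch; components
allocated to the sub-bands in proportion to their log-width), with
per-component power ∝ 1/f so that per-octave power falls 3 dB/octave.
The notch band 1.6–2.4 kHz contains no components at all.  The masker is
regenerated per trial.

Speech-on-speech (SRM) trials are represented at the trial/scoring level:
a structured record of call sign, color/number keywords (4 × 8 response
grid), levels, and azimuths (0° colocated; maskers ±45° separated), plus
a schematic tone-complex placeholder waveform.  Speech audio and
head-related spatialization are intentionally out of scope; SRM
psychometrics enter through the observer model in TMR.

## Simulated observers

Observers are psychometric functions on the task's adaptation domain:

    p(correct | x) = γ + (1 − γ − λ) · F((x − α)/β)

with F logistic by default (Weibull optional), γ = 0.5 for 2AFC and 1/32
for the color/number grid, lapse λ default 0.02 (0 in analytic tests).
The domain is log2(native units) for exponential tracks, dB for linear
tracks, negated masker level for the tone-in-noise pair (so that larger
always means easier), and TMR for speech.  Observers never analyze
audio; they are the harness for verifying the procedures, which is also
why the session runner does not render waveforms per trial.

## Reliability analysis

Native thresholds are mapped to analysis units — log2(ms) for gap,
log2(Hz) for FM, mid-to-peak dB for the modulation tests, TMR
(45 dB SPL target minus masker level) for tone-in-noise, TMR directly
for speech.  Outlier rejection keeps a value iff it deviates by at most
3 sample SDs from the per-assessment, per-session mean, computed in a
single pass including the candidate (re-applying the rule to survivors
could reject more; it is deliberately not iterated).

Per assessment, agreement between sessions is summarized Bland–Altman
style: bias = mean(session 2 − session 1), 95% limits of agreement at
bias ± 1.96 sample SD of the differences, alongside Pearson r (two-sided
p, no multiplicity correction), the paired t-test, paired Cohen's d
(bias / SD of differences), and df = pairs − 1.  Composite scores are
per-subject means of per-assessment z-scores (the ten tests feed the
composite; the derived spatial-release metric does not), with internal
consistency summarized by Cronbach's α (computed on the z-scored matrix,
where covariance α coincides with standardized α).

The depth-metric conversion to the linear-modulation convention,

    20·log10((10^(m/10) − 1) / (10^(m/10) + 1)),

equals 20·log10(tanh(m·ln10/20)); it is strictly increasing, negative,
and concave, so converting a cohort's mean depth always gives a value at
least as high as averaging converted per-subject depths (Jensen gap) —
the pipeline supports both orders.

## Synthetic cohorts

The generator emulates a two-session study: per assessment, subject
abilities are Normal(mean, between-SD) in analysis units; each session
adds Normal(0, within-SD) noise and session 2 an optional learning
shift; an optional outlier fraction displaces abilities by 3.5–5
between-subject SDs.  Default population presets place means, spreads,
and sub-dB session shifts at magnitudes typical of young normal-hearing
cohorts; they are presets for realistic-looking output, not fitted
ground truth.  Observer slope β is fixed per assessment (0.5 log2 units
or dB for the 2AFC tasks, 2 dB for level-based tasks) since threshold
studies rarely constrain it.

Two dataset paths exist.  The threshold-level path emits session
abilities directly as measured thresholds and is the right tool for
statistical-recovery experiments (hundreds of replicate cohorts); the
full-procedure path runs every staircase and progressive track through
the observer model, adding the procedure's own estimation noise.
Recovery experiments in the test suite use n = 150 subjects and 50–200
replicates; the full-procedure path is exercised at small n.

**What the generator does not model:** a general auditory factor
correlating abilities across assessments (columns are independent, so
the default cohort's Cronbach's α is near zero and the composite's
between-session r only beats single tests when a shared ability is
present); non-Gaussian threshold distributions; practice effects beyond
a constant session shift; heteroscedastic session noise (spread growing
at worse performance); and any dependence of lapse rate on task.
Passing recovery tests therefore demonstrates that the *pipeline*
(procedures + statistics) is unbiased and calibrated under its own
generative assumptions, not that real cohorts satisfy those assumptions.

## Numerical conventions and edge cases

- Level round trips are exact to 0.01 dB; WAV float32 round trips are
  bit-exact, PCM16 within 2⁻¹⁵.
- Exponential tracks with a 0 lower bound never reach 0 by multiplicative
  steps; the geometric-mean estimator rejects nonpositive reversal values.
- A responder pinned at ceiling or floor never reverses; simulation caps
  tracks at 1000 trials and reports the clamped terminal value (the
  bound), flagged by `finished=False` on the track state.
- Zero-variance inputs: Bland–Altman returns t=0, p=1, d=0; composite
  scoring raises, naming the degenerate assessment; outlier rejection
  keeps everything when the SD is 0.
- Practice trials (5 per assessment, unscored) are placed four stage-1
  up-steps easier than the staircase start, clamped to bounds.
- Assessment order: the two tone-in-noise tests run first, then the
  temporal-fine-structure, modulation, and speech blocks with a seeded
  shuffle inside each block.

## Known limitations

- SRM audio is schematic; conclusions about speech stimuli are limited to
  the trial/scoring level.
- The 6-reversal staircase estimate retains a small start-transient bias
  (of order one stage-2 step) even with the bookkeeping-first convention;
  tracks started far above threshold with very steep observers recover
  the asymptote in position but not in percent-correct terms, because the
  steep slope amplifies that residual offset.
- Cronbach's α and battery-level correlations on default synthetic
  cohorts are not comparable to human data (no general factor; see
  above).
- The headphone/noise experimental manipulations enter only through their
  procedural difference (1.5:1 vs 2:1 step ratio) and as condition
  labels; the acoustics are out of scope.
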