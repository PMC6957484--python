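# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the pipeline.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

A subject wears a single-lead ECG patch (250 Hz) with a triaxial
accelerometer and a flash CGM sampling interstitial glucose every 15 minutes.
Analysis is restricted to the nocturnal window (midnight–9 AM) to avoid
confounding by the circadian lengthening of cardiac repolarisation and by
daytime activity.  Low glucose (LGL) is glucose < 4.0 mmol/L; normal (NGL) is
4.0–7.5 mmol/L.  A subject qualifies when at least 10% of their readings fall
below 4.2 mmol/L and the 80th percentile of readings is below 7.5 mmol/L.
The detector is personalised: one model per subject, trained on a subset of
nights and tested on held-out nights, never pooled across subjects.

## Synthetic-data generator

Real recordings of this kind are private, so the generator is a first-class,
tested component rather than a fixture.

**Beats.** Each heartbeat is a sum of five Gaussians (P, Q, R, S, T) with
per-subject amplitudes (mV), centers (ms relative to R) and widths (ms).
Defaults: P(0.15 mV, −180 ms, 20 ms), Q(−0.20, −25, 8), R(1.20, 0, 10),
S(−0.25, 25, 8), T(0.35, 260, 35).  The T center/width were chosen so that
the T-offset point (where the wave decays to 10% of its peak) stays inside
the 160-sample beat window even after QT prolongation, which keeps the
feature extractor's closed-form truth well defined.  A Gaussian-wave model
was preferred over a dynamical (ODE) beat model because it realises exactly
the morphology effects of interest and every downstream quantity (peak
positions, amplitudes, QT) has a closed form to test against.

**Glucose→morphology coupling.** Below an onset threshold (default
4.0 mmol/L) the T center shifts by +40 ms (QT prolongation), the T amplitude
is scaled by 0.7 (flattening) and the P amplitude by 1.3 (more pronounced P,
as seen in some subjects).  The coupling is a step, not a ramp: it matches
the dichotomous labelling and keeps oracles exact.  Effect magnitudes are
configurable; the defaults are deliberately strong ("strong coupling") and
are not claimed to match any human effect size, for which only directions
are established.

**Glucose.** One-minute grid over the night: baseline 5.5 mmol/L plus
Gaussian noise smoothed with a 20-min kernel (sd 0.25 mmol/L) plus
raised-cosine dips placed by a Poisson process (default 3 dips/night, depth
2.8 ± 0.3 mmol/L, duration 60 ± 10 min), clipped to [2.2, 12] mmol/L.  These
defaults give an eligible subject with roughly 15–20% of nocturnal readings
below 4.2 mmol/L at full scale, comparable to the low/normal beat ratios an
eligible free-living subject produces.

**CGM observation.** reading(t) = true(t − lag) · (1 + ε) on a 900-s grid
with lag 300 s.  ε is zero-mean Gaussian truncated at ±3σ, with σ calibrated
so that E|ε| equals the MARD target (11.4% by default):
σ = (MARD/100) / (√(2/π) · c₃), where c₃ ≈ 0.9916 corrects for the
truncation.  Only the MARD of the reference sensor is known, not its error
distribution; multiplicative truncated-Gaussian noise is the minimal model
consistent with a relative-error metric.

**ECG rendering.** Beat times follow an instantaneous-HR model
(RR = 60/HR, HR ~ N(60, 5) bpm truncated to [35, 180]).  Waves are summed
with ±7σ support (truncation error < 1e−10 mV, tested at 1e−9), then
baseline wander (0.1 mV sine at 0.25 Hz), white noise (0.02 mV) and
0.5-s artifact bursts (1/hour, σ 1 mV) are added.  Accelerometry is
simulated directly at 1 Hz in g units (rest posture with 30-s movement
bursts), since the VMU definition already averages over one second.

**Ground truth.** Every night stores its beat times and the exact wave
parameters used per beat, so detectors and feature extractors can be scored
against the generating truth.

**What the generator does not emulate** — realistic HRV spectra, respiratory
modulation, arrhythmia, electrode-contact drift, daytime activity, graded or
lagged morphology responses, and subject-specific CGM bias.  Tests passing on
this generator therefore demonstrate that the pipeline recovers a known
coupling under realistic sampling/noise arithmetic; they do not demonstrate
clinical performance on human data.

## Preprocessing

R peaks: Pan–Tompkins-style pipeline (5–15 Hz band-pass, derivative,
squaring, 150-ms moving integration, adaptive threshold at 20% of the 99th
percentile, 200-ms refractory period, peak refinement on the band-passed
signal).  Any detector recovering ≥99% of truth beats within ±2 samples on
default-noise simulator output is acceptable; the property is tested.

Quality: 5-s windows pass when the implied HR lies in [30, 200] bpm and the
40-Hz high-pass residual RMS is below 0.05 mV.  This is a surrogate for the
patch device's proprietary "HR confidence = 100% and ECG noise < 0.001"
gates, whose units are unspecified; no equivalence is claimed.

Beats: window [R−60, R+99] (160 samples = 640 ms); boundary beats are
skipped, never padded (padding would distort z-statistics).  Each window is
z-normalised and decimated keeping indices 2, 5, …, 158 — exactly 53 points.
The decimation offset is a convention: keeping every 3rd sample from offset 0
would give 54 points; offset 2 gives the documented 53 with symmetric
coverage.  The 53-point series is a pure subset of the z-scored window (no
interpolation), so its own mean/sd deviate slightly from 0/1; the z-contract
is enforced on the full window.  Each beat's activity value is the VMU of the
1-s epoch containing its R time.

## Dataset construction

CGM readings are treated as step functions valid until the next reading; a
beat is matched to the reading covering (r_time + 300 s), compensating the
sensor lag.  Guard band [4.0, 4.2) applies in training mode only; at test
time those beats count as normal (per the NGL definition), and readings above
7.5 mmol/L are excluded from metrics and counted.  Nights are split so that
train and test each contain low-event nights (an event must last ≥5 min);
validation is a seeded 20% sample of usable training beats, held out of
gradient batches to keep the early-stopping signal honest.  When lows fall
below 25% of normals, normals are downsampled without replacement to 4× the
lows — restoring exactly the trigger boundary is the minimal intervention;
no oversampling is ever used.  Sequences for the CNN+LSTM are the first 200
beats of non-overlapping 5-min excerpts aligned to each night's first quality
beat; an excerpt is dropped if it has <200 beats (HR ≤ 40 bpm), mixes labels,
touches excluded glucose ranges, or its glucose event spans <5 min.  Event
durations are measured on the beat stream, so events censored by the night
boundary count as short — a conservative choice.

## Models and training

Both networks are float32 NumPy with hand-written backprop (verified against
numeric gradients in the test suite).  Convolutions are length-preserving
(stride 1, "same" zero padding): with no pooling anywhere, the last conv
layer's feature maps index the 53 beat positions directly, which is what
makes 1-D Grad-CAM meaningful without upsampling.

* CNN: 15 × [conv(3, 50) → BN → ReLU] → flatten (2650) → dense(30) → ReLU →
  concat activity scalar (31) → dropout 0.5 → dense(2) → softmax.  The
  activity scalar is z-scored with training-set statistics and joins after
  the dense activation.  Parameter count 186,994 (tested against the closed
  form).
* CNN+LSTM: 5 × [conv(3, 50) → BN → ReLU] → global average over positions →
  50-vector per beat; encoder weights shared across the 200 time steps;
  LSTM(400) → dropout 0.6 → dense(2) → softmax, output at the last step only.
  Global average pooling is the smallest faithful reading of "fixed-length
  vector representation" and keeps CPU training tractable.  The activity
  covariate is omitted for the sequence model (the architecture diagram shows
  beats only); the asymmetry is deliberate.

Training: Xavier-uniform weights, zero biases, Adam (1e-4, β₁ 0.9, β₂ 0.999),
cross-entropy, batch 200 (CNN) / 30 (CRNN), validation AUC (Mann-Whitney
rank form) every 100 steps, early stop after 10 evaluations without a strict
improvement of more than 1e-6 (the epsilon avoids float-noise resets), best
snapshot restored.  BN uses momentum 0.9 and ε 1e-5; inference uses running
statistics, making predictions deterministic and batch-size independent.

**Desk-scale profile.** The full protocol caps training at 25,000 steps
(`models.FULL_PROTOCOL_MAX_STEPS`).  The package's default experiment profile uses 6
simulated nights of 3 h and a 1,500-step cap (the acceptance experiment
converges by ~500 steps); null-control runs use 4 nights of 2 h and 200
steps, since chance-level AUC is independent of training length.  Shortened
nights keep the per-night dip count, so the low fraction is higher than at
full scale; full-scale defaults (10 nights, 9 h) reproduce realistic
low/normal ratios.

## Explanation

Grad-CAM for 1-D signals: channel weights α_k = (1/53) Σ_i ∂y_c/∂A_k[i]
(the 2-D double sum of the original formulation reduces to one positional
sum), map = ReLU(Σ_k α_k A_k), normalised per beat to max 1 (zero maps stay
zero).  y_c is the pre-softmax class score; A is the post-ReLU output of the
last conv layer.  Per-beat (not per-subject) normalisation makes the 0.9
histogram threshold comparable across beats.  Saliency histograms count, per
position, the maps strictly exceeding 0.9.  t-SNE embeds the 30-unit dense
activations (a flag selects the flattened last-conv maps instead) on a
class-balanced subset (normals downsampled to match lows, seeded), with
perplexity 30, 1000 iterations, PCA initialisation and a fixed seed.

## Evaluation

Per-beat probabilities are aggregated into non-overlapping 10-min windows
aligned to the night start; empty windows are skipped.  A window is low when
at least half its beats vote low — the tie favours the alarm, since missing
an event costs more than a false alarm.  Certainty is dark/light by whether
the mean winning-class probability exceeds 0.7.  Interval ground truth is the
majority of CGM-derived beat labels; windows whose excluded/mixed beats
exceed half are dropped from interval metrics and counted.  Metrics use low
as the positive class; AUC is the Mann-Whitney rank statistic with midranks.
The nightly timeline shows the CGM trace with a ±10% uncertainty band and
one coloured point per interval (red/green × dark/light).

In simulation experiments, held-out performance is reported both against the
simulator's true glucose (parameter recovery — did the model learn the
injected coupling?) and against the noisy CGM labels (what a deployment
would measure).  CGM error flips labels near the threshold, so the
CGM-labelled AUC is bounded away from 1 even for a perfect detector; the
truth-labelled AUC is the meaningful recovery metric.

## Statistics

Features per beat, on the raw mV window (amplitudes are meaningless after
z-scoring): Q, R, T amplitudes from the window-median baseline; QT interval
peak-to-peak (Q-peak to T-peak by default; an R-to-T convention is a flag,
since "peak to peak" leaves the anchor ambiguous); R/T amplitude ratio;
T slope through the T peak and the T offset (first sample decaying to 10% of
the T amplitude).  The T peak is searched 120–396 ms post-R (bounded by the
window); beats with |T| < 0.05 mV or no offset are excluded and counted.

Intra-subject: two-sided Mann-Whitney per feature on class-balanced samples
(majority class downsampled, seeded); normality screened by Shapiro-Wilk on
subsamples of ≤5000 (the test is unstable at very large n).  Inter-subject:
Kruskal-Wallis omnibus per feature; when p < 0.05, all-pairs Dunn z-tests on
pooled tie-corrected ranks with Holm adjustment (a correction is standard
practice even where unspecified; Holm is conservative and assumption-free).

## Numerical and degenerate-input choices

float32 network arithmetic with float64 accumulation in batch-norm
reductions; zero-variance beat windows rejected rather than normalised;
constant statistical samples reported as degenerate with p = 1 rather than
erroring; empty accelerometer epochs carry the previous VMU forward; CGM
readings floored at 0.1 mmol/L; unordered CGM files are sorted with a warning
(an error under `--strict`).

## Limitations

The NumPy trainer is single-threaded BLAS-bound (~0.2–0.3 s per 200-beat
batch through the 15-layer CNN on one CPU core); the full 25,000-step
protocol is available but takes hours.  The simulator's step coupling makes
the classification task easier than graded human responses; null-control and
localisation tests bound leakage and attribution artifacts but not clinical
generalisation.  Only 250 Hz input is accepted — resampling is out of scope
by design.
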