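# Methods

This note documents the modeling choices behind `duincoder`: what each
stage assumes, which parameters matter, what the synthetic data does and
does not emulate, and where the design was genuinely open.

## Problem setting

The task is one-class (novelty) detection: decide whether a journey was
driven under alcohol impairment using only a model of *normal* driving.
Labels enter the pipeline in exactly two places — a guard that refuses
drunk-status records at training time, and the evaluation stage. Per-frame
decisions are aggregated to a journey-level score, the anomalous
proportion (AnoP): the fraction of frames whose behavior falls outside the
learned boundary of normal driving.

## Signals

Telemetry is six channels at a canonical 10 Hz: speed (km/h), steering
([−1, 1]), throttle ([0, 1]), brake ([0, 1]), lane-center deviation (m),
yaw rate (rad/s). Each frame owns one window of `L = round(duration·rate)
+ 1` frames (inclusive endpoints, so 10 s ⇒ 101 frames), edge-padded at
record boundaries so the number of prediction sites equals the number of
frames. Windows are flattened feature-major (all L frames of channel 0,
then channel 1, …); the order is arbitrary but fixed, documented and
tested, since any lossless order is equivalent for dense layers.

Channels are z-scored with pooled per-channel moments of the training
records. A zero-variance channel is a hard error by default — it almost
always indicates a degenerate generator or a stuck sensor — with an
opt-in `std_floor` for deliberate constant-channel experiments. The
package also ships a fixed set of z-score constants
(`duincoder/data/default_stats.yaml`) for use when no training data are
available to derive them.

Record-level splitting uses largest-remainder rounding of the 7:2:1
proportions after a seeded shuffle of the id-sorted record list, making
the split a pure function of (ids, ratio, seed). An optional stratified
mode applies the same rule within each (route, status) stratum; the study
driver `run_study` uses it so that small desk-scale test splits always
contain both statuses.

## Driver model

The generative model is a VAE whose latent prior is *conditioned on a
categorical code* rather than fixed: a LeakyReLU MLP and a combining
linear layer produce `Ncat` logits, a Gumbel-Softmax layer samples a code
`y` (soft simplex samples during training at temperature 1.0, exact
one-hot at inference), and an affine head maps `y` to a per-category prior
N(μ_y, σ_y²). The intent is to let distinct maneuver/scenario regimes
(cruising, stopping, cornering) own distinct latent priors instead of
forcing one standard normal over all of them. A single `Ncat`-way
categorical is used; a product of several independent categoricals would
be a plausible alternative reading of the architecture, but the simpler
variant is implemented.

The encoder consumes `[x, y]` and yields the posterior N(μ_z, σ_z²);
`z = μ_z + σ_z ⊙ ε` decodes to the central `L′` frames of the window
(default `L′ = L`; a central crop is supported). Losses:

- `L_recon`: **mean** absolute deviation over the reconstruction span.
  The mean (not sum) keeps loss magnitudes comparable across window-size
  experiments.
- `L_gauss`: single-sample estimate of
  `log p(z|posterior) − log p(z|prior)`, summed over latent dimensions and
  averaged over the batch; its expectation is the Gaussian KL divergence,
  and the test suite verifies this against the closed form.
- Variant **G** minimizes `L_recon + w·L_gauss` with `w` a symmetric
  raised-cosine cycle `w(e) = ½(1 − cos 2πe/P)`, period P = 200 epochs,
  preventing the ELBO term from collapsing the latent code early in
  training. Variant **R** minimizes `L_recon` only and is the stricter,
  better-separating detector; it is the default.

Numerical choices: log-variances are clamped to `[log 1e−8, 8]` (a
variance floor of 1e−8), gradients are zeroed outside the clamp; weights
use He initialization; the prior head starts at exactly zero so every
category begins at the standard normal; Adam runs at lr 0.0004 decayed
×0.95 every 50 epochs with batch 256 and a per-epoch reshuffle. Validation
every 20 epochs computes, per window, the minimum over K = 32 sampled
reconstructions of the mean absolute deviation, and the checkpoint with
the lowest mean score is kept (earliest epoch wins ties, for
determinism). All networks, gradients and updates are plain-numpy, making
every run bit-reproducible from `random_state`; the hand-derived backward
pass was verified against central finite differences during development
and is covered by the optimization-sanity test.

Default widths (hidden 512/256, Ncat 16, latent 64) are desk-scale
choices — the architecture's widths are not externally prescribed — and
every width is a constructor parameter. The smoke profile and the
acceptance conditions use smaller widths (64–128) because at these data
sizes the extra capacity changes nothing but the runtime.

## Detector

For each frame, K = 32 stochastic reconstructions are drawn (categorical
head → posterior → reparameterize → decode). The frame's novelty feature
is the per-channel **minimum deviation**: the elementwise minimum across
samples of the mean absolute error over the span. The elementwise minimum
(rather than the channel values of the best-total sample) gives a clean
monotonicity contract — more samples can only lower the deviation — while
the best-total sample's reconstruction is retained separately for
explanation displays. Deviations are computed on z-scored data because the
channels' units are incommensurate; explanation output denormalizes.

The boundary is a scikit-learn isolation forest (100 trees, subsample 256)
on the 6-dimensional deviation vectors of normal training frames, with
`contamination` (default 0.01) setting the fraction of training frames
allowed outside. A scalar mode (total deviation only) is available for
comparison. Frames outside the boundary are flagged; AnoP aggregates
flags per journey, and a journey verdict uses a configurable AnoP
threshold (default 0.05; the threshold is presentation-level — evaluation
works on the AnoP distributions themselves).

One calibration note: the flagged fraction on the *training* frames equals
the contamination by construction, while held-out normal records typically
come in slightly below it, because the training score quantile is set by a
few hardest segments (stop transitions, sharp curvature) that a short
held-out journey may not contain. The acceptance checks cover both
quantities.

## Evaluation

Group summaries report min/median/max/IQR after one pass of Tukey 1.5·IQR
trimming (the trimming rule was an open choice; Tukey is the boxplot
convention). Separation is measured by rank-based ROC AUC over per-record
AnoP (drunk positive; ties count ½ — verified against exhaustive pair
enumeration) and a two-sided **Welch** t-test (unequal variances are the
realistic case for these two groups; the equal-variance variant was the
other open option). Supervised frame-level baselines (LDA, AdaBoost,
gradient-boosted trees, SVM, random forest) train on a record-balanced
subsample of both statuses; a plain Gaussian-prior VAE baseline trains on
normal windows and reuses the same minimum-deviation + isolation-forest
stage. An ablation harness re-runs the full pipeline over grids of route
subset, window length, contamination, training-data proportion and loss
variant.

## Simulator

The synthetic generator exists so the pipeline is testable end to end
without the original (private) driving-simulator data. It is a kinematic
single-track vehicle (wheelbase 2.7 m, max wheel angle 0.5 rad) driven by:

- a lane-keeping controller: PD feedback (k_p = 1.0 s⁻², k_d = 1.6 s⁻¹)
  on lane error measured with a 0.2 s sober reaction delay, curvature
  feedforward, and AR(1) noise in lateral-acceleration space
  (σ = 0.4 m/s², ρ = 0.9) so lane-keeping quality is speed-invariant;
- a longitudinal controller: proportional speed tracking (0.4 s⁻¹) with
  drag/rolling-resistance feedforward and AR(1) accelerator noise,
  saturating into throttle/brake ∈ [0, 1].

Three route archetypes differ in target-speed plans, curvature events and
stop events: accident-prone urban (dense events, 120 s), urban (moderate,
120 s), highway (fast, gentle, 180 s). Impairment modifies only the
driver: +0.4 s reaction delay, ×2 steering and speed noise, and a 0.3 m /
6 s sinusoidal lane weave. The null impairment (0, ×1, 0 m) reproduces
the normal branch bit-exactly. The defaults produce clearly degraded but
controlled impaired driving (lane-deviation std roughly 0.25 m normal vs
0.9 m impaired) that is not separable by speed alone.

What the simulator does *not* emulate: traffic agents, collisions, road
surface, driver individuality beyond seed noise, fatigue/time-on-task
drift, or the specific dose–response of alcohol. Consequently, passing
tests demonstrate that the pipeline detects a *behavioral contrast of this
kind* (slower, noisier, weaving control), not that it reaches any
particular accuracy on real impaired driving; the synthetic contrast is
stronger and cleaner than real data, which is why record-level AUC
saturates near 1.0 here.

## Desk-scale study conditions

The shipped acceptance/study conditions are: 15 records per route × status
(45 normal + 45 impaired) at default durations, 10 s windows, variant R
with widths 64–128, Ncat 8, latent 16, 120 epochs, training capped at
4096 subsampled windows and validation at 1024 (the isolation forest is
still fitted on *all* ~46k normal training frames), K = 32 samples,
contamination 0.01. These sizes keep a full run around a minute or two on
one CPU while leaving every stage of the method intact.

## Known limitations

- Gumbel-Softmax uses a fixed temperature (1.0) with no annealing; the
  straight-through estimator is not used (soft samples in training).
- The categorical prior head receives gradient only through the ELBO term,
  so in variant R the per-category priors stay near their initialization;
  the code `y` still shapes the encoder input.
- Checkpoints store parameters and config but not the optimizer state;
  training cannot be resumed mid-run, only reproduced from the seed.
- The isolation-forest boundary is refitted per study; boundaries are not
  transferable across normalization statistics.
- matplotlib-based boxplot rendering is deliberately left out of the
  tested surface; all evaluation outputs are CSV/JSON.
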