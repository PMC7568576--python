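# Methods

## Scope and model of the data

The package targets the standard processing chain for cardio-mechanical
inertial recordings: six channels (SCG_X/Y/Z from a chest-worn
accelerometer, GCG_X/Y/Z from its gyroscope), sampled at a default of
256 Hz. Real cohorts of this kind are small (tens of subjects) and
class-labelled per subject, so the package ships a synthetic cohort
generator whose defaults mirror that setting: 21 AS and 13 non-AS
subjects for the binary task, four AS sub-classes (AS only, AS+MI,
AS+MS, AS+TR) for the multi-class task, several minutes of sitting-rest
signal per subject.

## Synthetic recordings

Each subject draws, from a seeded generator, a heart rate (50–95 bpm),
per-channel gains (dorso-ventral accelerometer axis SCG_Z and
head-to-toe gyroscope axis GCG_Y strongest), three beat-oscillation
center frequencies (~7–10, 12–16, 18–23 Hz), a sensor-noise level
(sd 0.30–0.40 in the arbitrary signal units) and a motion-artifact rate
(1–3 per minute). A recording is

* a **carrier**: the sum of the three tones, amplitude-modulated by a
  beat envelope (Gaussian windows at beat times, modulation floor 0.8).
  The floor models the continuous chest-wall micro-vibration between
  beats; it is also what keeps the clean-signal RMS envelope stable
  enough (max ≲ 1.4× median across realizations) for the 1.5×-median
  artifact threshold to act only on artifacts;
* a **murmur** for the AS family: band-limited noise in 3–9 Hz (below
  10 Hz, where stenotic vibration concentrates), gated by a systolic
  envelope with a continuity floor of 0.7 (configurable down to fully
  beat-gated bursts), gain ≈ 0.25 of the channel gain, zero for non-AS.
  The AS sub-classes add a second band-noise component in disjoint
  bands (10–14, 14–18, 18–23 Hz) so four-class separation is learnable;
* white sensor noise, plus **motion artifacts**: Poisson-counted noise
  bursts at 12× the channel gain, 0.5–2 s long, hitting all channels at
  once. Burst onsets and durations snap to the 0.5-s RMS grid, so every
  envelope cell an artifact touches holds a full-amplitude chunk of it
  and the rejection oracle ("a window overlapping a burst must fail the
  RMS test") holds exactly by construction rather than up to edge
  effects.

The beat model is explicitly non-physiological — windowed tones, not a
cardiac-mechanics template; no ECG, respiration or hemodynamics; units
are arbitrary since no sensor amplitude scale is modeled. Passing tests
therefore certify the pipeline's statistical behavior (filters,
thresholds, selection, validation schemes), not clinical performance.
Subject-level random effects (rates, gains, murmur strength) make
leave-one-subject-out validation strictly harder than segment-level
splits, reproducing the expected ordering between the two schemes.

For isolating the selection and classification layers there are direct
fixtures: feature tables with a planted informative subset at a chosen
effect size, tables with subject-level random intercepts, and separable
synthetic scalogram images with class-specific frequency-row bands.

## Pre-processing

The band-pass is a 4th-order Butterworth (0.8–25 Hz) applied
forward-backward (`sosfiltfilt`), i.e. zero-phase, preserving waveform
morphology; its effective amplitude response is the square of the
one-pass response (unit gain at 5 Hz, < 0.02 at 40 Hz). The RMS
envelope uses non-overlapping 0.5-s windows (window = step), making its
length deterministic; candidate 10-s segments tile the recording from
t = 0 without overlap (no duplicated data across folds later). A
candidate is accepted iff the maximum envelope value inside it is
≤ 1.5× the median envelope of the whole recording, per channel: a
single burst disqualifies a window. When features from several
channels are concatenated, a window must be accepted on every channel
involved (intersection rule). Recordings shorter than one segment
yield an empty segment list, not an error.

## Morse-wavelet CWT and features

The generalized Morse wavelet is evaluated directly in the frequency
domain, ψ̂(ω) ∝ ω^β exp(−ω^γ) for ω > 0 (analytic), with γ = 3 and
β = 20 (time–bandwidth product 60). Scales map each grid frequency to
the wavelet's peak frequency (β/γ)^(1/γ); the peak value is fixed at 2
so a unit-amplitude real sinusoid at a grid frequency yields ridge
magnitude ≈ 1 (an L1-type normalization). Analysis frequencies are
log2-spaced with 16 voices per octave over 0.79–25.39 Hz (81
frequencies at the default; the count is floor(voices·log2(f_max/f_min))+1,
clipped to the band). Segments are zero-padded to the FFT length; no
cone-of-influence masking is applied. Tone-localization error is under
one grid bin across the band (verified 1–24 Hz).

Per frequency row, five statistics are taken along time with fixed,
documented estimators so expected values are exact: MEAN arithmetic;
MED and IQR from linear-interpolation (type-7) quantiles; STD with the
population convention (divide by N). Feature names encode
`<CHANNEL>_<STAT>_<freq at 2 decimals>` and parse back exactly, which
is what the distribution summaries rely on.

Scalogram images are min-max normalized per segment; the grayscale path
resizes bilinearly to 600×800×1 (the custom CNN's input), the RGB path
uses a 128-level parula-style lookup table (an approximation of the
proprietary parula ramp, interpolated from published anchor colors) at
224×224 for transfer-learning backbones. A constant scalogram cannot
be normalized and renders as zeros with a warning.

## Elastic-net selection

Features are z-scored on the table being fitted. Selection fits
elastic-net logistic regression (ℓ1-ratio 0.5 by default) over a
penalty path: the path's strongest penalty sits just below the
activation threshold (KKT condition at zero coefficients), so the
empty model is always a candidate, and spans three decades upward with
25 points. Each penalty is scored by k-fold (default 5)
cross-validated deviance; the chosen penalty is the strongest one
within one standard error of the minimum (1-SE rule), favoring stable
sparse sets. The final model is refit on the full table at that
penalty; selected features are its nonzero coefficients. Multi-class
tables run one-vs-rest per class and take the union of the selected
sets. Constant columns are dropped with a logged warning;
single-class tables are an error.

With p ≈ n, single label permutations can carry genuine chance
predictability, so the null behavior of the selector (selecting almost
nothing) is a property of the permutation ensemble, not of every draw;
tests and the acceptance script therefore aggregate over 20
permutations. The reported dimension-reduction percentage is always
computed as 100·(1 − n_selected/n_original), never stored as a
constant.

Distribution summaries count the selected set by frequency band
(< 10 Hz, 10–20 Hz, > 20 Hz), statistic, and source channel, each with
a Pareto curve (cumulative share over categories sorted by descending
count, ties broken alphabetically).

## Classification and validation

Four families (DT, RF, MLP, XGBoost) share one grid-search harness:
exhaustive sweep, inner k-fold accuracy as the criterion, ties broken
by first-in-grid order, refit on the full training table. Default
grids are deliberately small and conventional (tree depth /
min-split; forest size / depth; one or two hidden layers and learning
rate; boosting rounds / depth / learning rate); one-point "fast" grids
exist for runs where tuning is not the question. The MLP architecture
is the package's own default — (64,) or (128, 64) hidden units — since
no canonical choice exists for this task.

Leave-one-subject-out holds out all segments of one subject at a time;
feature selection (when enabled) and grid search run strictly on the
remaining subjects; predictions are pooled over all held-out segments
and metrics computed from the pooled confusion, matching segment-level
reporting. Leave-data-out is a stratified segment-level hold-out
(default ratio 0.2) that permits subject overlap between sides and is
therefore expected to score higher on subject-structured data — the
ordering is asserted as a tendency over seeds, not per draw. Metrics
are precision, recall, F1 and accuracy from confusion counts
(one-vs-rest per class in the multi-class case); zero denominators
report 0 with a logged warning.

## The custom CNN

The architecture is a fixed chain over 600×800×1 grayscale scalograms:
Conv(5@3×3) → Conv(5@2×2) → MaxPool(2×2/2) → Conv(5@3×3) → Conv(5@5×5)
→ MaxPool(5×5/5) → Flatten(22,620) → Dense(256) → Dense(32) → Dense(1,
sigmoid), ReLU between layers, valid padding throughout — 5,800,248
trainable parameters. The single input channel and the 600×800 size
are forced by the layer arithmetic itself (a 3×3 conv with 50
parameters and a 798×598 output admits no other input); RGB rendering
belongs to the transfer-learning path only, whose head is
Dense(256) → Dense(32) → Dense(1, sigmoid) on top of an external
backbone (weights never bundled; executing a pretrained backbone is
out of scope).

Shape inference and parameter counting are exact integer arithmetic
(conv: kh·kw·C_in·F + F; dense: in·units + units; valid-padding and
floor-division pooling formulas), independent of any training
framework. Training runs on an in-repo numpy engine implementing
exactly this layer set with im2col convolutions, Adam (default
learning rate 8e-4), and sigmoid binary cross-entropy folded into the
loss for stability; gradients are verified against finite differences,
and the engine's materialized weight-array sizes cross-check the
calculator's counts. Training-scale runs re-infer the same chain at a
reduced input (60×80 in tests), hold out 20% of images (stratified),
run k-fold cross-validation on the remainder (10 folds by default; 2–3
in smoke tests), then fit a final model on all non-held-out images —
the hold-out set is never touched before prediction. Max-pool
gradient ties split evenly; epochs default to 30 with early stopping
on fold-validation loss (patience 5) or on training loss < 1e-3 when
no validation set exists.

## Problem sizes and numerical choices

Tests and the acceptance script use deliberately modest sizes chosen
once: 60-s recordings for the 34-subject cohort runs (132 accepted
windows, 2,430 features), 300-s recordings for segmentation checks,
200×200 planted tables for selection, 200 images at 60×80 for CNN
smoke training. Determinism: every stochastic component takes an
explicit seed (numpy `default_rng`; scikit-learn / XGBoost
`random_state`; single-threaded fits), and identical inputs plus seeds
reproduce outputs bit-for-bit.

## Known limitations

* The generator's realism stops at second-order statistics: no beat
  morphology, respiration coupling, sensor drift, or inter-channel
  phase physiology; artifact snapping to the RMS grid trades realism
  for an exact rejection oracle.
* The elastic-net path is logistic (classification deviance); no
  survival or ordinal variants.
* The numpy CNN engine is for smoke-scale verification, not
  production training: stride-1 valid convolutions only, CPU-bound,
  float64.
* Multi-class CNN training is not implemented (binary cross-entropy
  head only), matching the scope of the image path.
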