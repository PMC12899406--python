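# Methods

## Problem and model

The package automates a piece of post-stroke upper-limb assessment: given one
robot-guided elbow reaching trial — 8 channels of surface EMG at 1 kHz and the
robot end-effector speed at 500 Hz — predict the FMA-UE elbow sub-score
s ∈ {0, 1, 2} jointly with the movement phase p ∈ {0 extension, 1 flexion},
encoded as a six-class label y = 2s + p. Trials come from a fixed protocol of
18 actions (3 directions × 3 distances × reach/return), indexed
direction-major, distance-minor, with odd IDs for reach-out and even IDs for
return.

The classifier (AMWFNet) operates on time–frequency images. Each preprocessed
channel is transformed with a complex Morlet wavelet (ω₀ = 6; PyWavelets
`cmor2.0-C` with C = ω₀/2π) at scales log-spaced over 20–450 Hz for sEMG and
0.5–50 Hz for kinematics, then standardized: power |W|² → log1p → bilinear
resize → per-plane min–max to [0, 1]. A trial yields 11 planes (8 muscles +
velocity, acceleration, jerk). Per branch, a shared-weight CNN encoder
(4 double-conv blocks, 1→32→64→128→128, BN+ReLU, 2×2 max-pool, global average
pool) maps each plane to a 128-d vector; channel-wise attention pooling
(128→64→1 MLP, softmax over planes) collapses the branch; a gating MLP
(256 hidden) over the concatenated branch vectors produces two logits whose
temperature-scaled softmax (τ = 2.5) gives convex modality weights; the fused
vector plus an 18-d one-hot action encoding (146-d composite) passes a
128-hidden, dropout-0.3 head to 6 logits. The default build has exactly
1,268,554 trainable parameters (~1.27 M, ~4.84 MB at float32).

Because global average pooling closes each encoder, the architecture (and its
parameter count) is independent of the scalogram resolution; 128×128 is the
reference resolution, and any multiple of 16 per side is accepted (four 2×2
pool stages).

## Preprocessing

* sEMG: 50 Hz second-order IIR notch with Q = 30, then 4th-order Butterworth
  band-pass 20–450 Hz, both applied forward–backward (zero phase) with
  reflection ("even") padding. Pad length covers the filter ring-down:
  ~2Q cycles of the notch frequency, 10 cycles of the band edge for the
  Butterworth stages, capped at T−1. Residual edge asymmetry of the notch is
  below 10⁻³ of signal scale for 1.5 s trials.
* Kinematics: speed is differentiated by central differences (one-sided at
  the boundaries); every channel is smoothed by a zero-phase 4th-order 20 Hz
  Butterworth low-pass followed by a 15 ms Gaussian-weighted moving average
  (window rounded to an odd sample count, σ = window/6, unit sum). Jerk is
  differentiated from the *smoothed* acceleration, so each differentiation
  stage sees a conditioned input.
* Segmentation cuts continuous per-(subject, stage) streams at manifest
  timestamps, rejects overlapping segments, and drops (with a logged warning)
  segments shorter than 0.25 s.

## Neural-network core

The network layers are a compact NumPy implementation with explicit
reverse-mode gradients: convolution as patch-matrix × GEMM in channels-last
layout, batch normalization with running statistics (momentum 0.1), max
pooling with cached argmax, linear layers, inverted dropout, softmax
cross-entropy, global-norm gradient clipping, and AdamW with decoupled weight
decay. All computation is float32 and fully deterministic under fixed seeds
(single-threaded BLAS). Layer semantics are tested against independent
oracles (`scipy.signal.correlate2d`, finite differences).

One initialization choice departs from plain He init: the gating MLP's output
layer starts with weights scaled by 0.01, so fusion begins near (0.5, 0.5).
With default-scale initialization the gate tends to collapse onto whichever
branch fits the training data faster during the first epochs, starving the
other branch; the near-uniform start lets both encoders develop before the
gate commits.

## Training protocol

Subjects are split 60/20/20 into train/validation/test before augmentation
(floor rounding for validation and test; 40 subjects → 24/8/8). An optional
stratified mode draws the split within each score stratum and guarantees, for
strata with ≥3 subjects, at least one validation and one test subject per
score — with few subjects an unstratified draw can otherwise leave a score
level entirely out of training.

Class balancing augments minority-score training trials up to the majority
count (multiplicity configurable): per-modality amplitude scaling in
[0.9, 1.1], a single shared time-warp factor in [0.9, 1.1] applied to both
streams by linear-interpolation resampling, and Gaussian noise (σ = 0.05 on
sEMG, 0.005 on velocity and acceleration, in the unit-scale amplitude
convention of the synthetic signals). Jerk is never noise-injected; it is
recomputed by differentiating the augmented acceleration. Validation and test
sets stay raw, and the balancing routine refuses non-training trials.

Optimization is two-stage: warm-up on robot-guided passive trials (lr 1e-3,
up to 100 epochs), then fine-tuning of the same weights on active voluntary
trials (lr 5e-4), with AdamW (weight decay 1e-4), batch 32, gradient clipping
at global norm 1.0, and early stopping on validation loss with patience 10
(best-validation weights restored). Per-epoch history records losses,
accuracies and mean gate weights.

## Synthetic cohorts

The study's clinical recordings are private, so a generator produces cohorts
with the statistical structure the pipeline assumes. Design principles:

* **Normalization-robust class structure.** Because each scalogram is min–max
  normalized, absolute amplitude carries no class information downstream. The
  score therefore modulates *structure*: movement decomposition (the speed
  profile interpolates toward a 3-sub-movement profile), 3–8 Hz tremor ripple
  riding on the movement, movement-time prolongation, tonic (spasticity-like)
  antagonist activity, sEMG burst fragmentation, and a low-frequency tilt of
  the sEMG carrier spectrum (median-frequency slowing). Per-score strengths
  saturate as 1 − exp(−effect) toward score-specific asymptotes, so the three
  scores remain separated at any `class_effect_size`, and an effect of zero
  switches the class signal off bit-exactly (the noise streams do not depend
  on the score).
* **Phase structure.** Which muscle set acts as agonist swaps between flexion
  and return, expressed as a co-activation amplitude ratio. The globally
  visible phase cue is a time-axis skew shared by all channels: reaching out
  decelerates into the target (speed peak early, long tail) while the return
  is ballistic (peak late). Fragmented-vs-tonic impairment structure sits on
  fixed per-muscle susceptibilities (distal muscles lean tonic, proximal lean
  fragmented).
* **Stages.** Passive (robot-guided) trials nearly normalize the kinematics
  (stage factor 0.1) but retain a reduced sEMG class signal (factor 0.6, with
  weaker voluntary drive) — spastic co-activation is observable under passive
  motion. Active trials carry the full effect.
* **Determinism.** Per-trial random streams are keyed by
  (seed, subject, action, trial index, stage), so cohorts are reproducible
  and extensible; subject-level log-normal gains add cross-subject amplitude
  heterogeneity.
* **Planted-signal options** restrict the class signal to chosen sEMG
  channels and/or one modality, for attention- and gate-recovery experiments.

What the generator does *not* emulate: motor-unit physiology, 2-D workspace
geometry, electrode artifacts, inter-session electrode shift, or label noise
in therapist scoring. Passing recovery tests therefore show that the
architecture can extract class structure of the planted kinds across unseen
subjects — not that it reaches any particular accuracy on clinical data.

## Desk-scale experiment sizes

The test suite runs the stochastic experiments at reduced scale, chosen once:
recovery cohorts use 20 subjects × 18 actions × 2 stages × 1 trial
(720 trials), 3 s trials, `class_effect_size` 2.5, 32 CWT scales and 16×16
scalograms; stage 1 runs 8 epochs and stage 2 at most 20. Interpretability
probes use 6-subject planted cohorts (8 epochs for attention recovery, 5 for
gate recovery), and ablations train 5 epochs per seed on the recovery
cohort's active stage. The architecture is unchanged at these sizes (GAP
makes it resolution-independent); only the input resolution and data volume
are reduced.

## Numerical and design notes

* Scale→frequency mapping uses f = ω₀·fs/(2π·a); rows are ordered low→high
  frequency; log spacing is the default (linear available).
* Constant scalograms (degenerate min–max) map to all-zeros.
* No cone-of-influence masking is applied; tests that probe localization stay
  away from plane edges.
* Macro metrics divide by the fixed class count (6); classes absent from the
  ground truth contribute zero, making small-sample reports deterministic.
* The Fisher discriminant ratio weights groups by size in both the
  between-group and within-group terms (within-group variances use ddof = 1);
  zero within-group variance returns +inf.
* The "no gating" ablation concatenates the two branch vectors and reduces
  256→128 linearly so the classifier head stays identical across variants.
* The ZC/SSC deadband defaults to 0 (textbook definition, configurable);
  MDF/MPF use a Welch spectrum with segment length min(256, T) and 50%
  overlap; the spectral arc length uses a 20 Hz cutoff with amplitude
  normalization; the jerk index is RMS jerk × duration² / peak speed.
* The raw-signal 1D-CNN baseline mirrors the fusion head exactly and swaps
  the 2-D encoders for per-channel 1-D double-conv blocks (kernel 9,
  channels 1→32→64→128→128, pool 2); a concatenation switch replaces the
  gate for parity with ablation comparisons.

## Known limitations

* Training at 128×128 resolution is computationally heavy in this pure-NumPy
  implementation (~seconds per batch); the package is sized for desk-scale
  experiments and method verification, not large-scale training.
* Batch normalization couples per-batch statistics to batch composition; with
  very small datasets the eval-mode (running-stat) accuracy can lag the
  train-mode accuracy.
* The synthetic class structure is intentionally strong at high
  `class_effect_size`; real cohorts will sit far closer to the class
  boundaries, and reported recovery accuracies say nothing quantitative about
  clinical performance.
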