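# Methods

## The scientific problem

Facial expressions of mice carry a readout of emotional valence: appetitive
and aversive stimuli drive opposing, stereotyped configurations of the
ears, whiskers, mouth and snout, while arousal-linked features such as
pupil diameter respond to any salient stimulus. `faceval` implements the
full analysis chain for this readout — appearance-based prototype
similarity, keypoint-geometry kinematics, learned classifiers and
embeddings with interpretability probes, and coupled fiber-photometry
analysis — validated end to end on synthetic cohorts whose ground truth is
known exactly.

## The synthetic cohort generator

### What it emulates

The generator renders a vector-schematic side view of a mouse face on a
square canvas (default 256 px; all length parameters scale linearly with
canvas size). The geometry is controlled by ten interpretable fields whose
construction points double as the 37 tracked keypoints (8 pupil, 4 eyelid,
5 ear, 5 nose, 3 mouth, 12 whisker = three whiskers × 4 points), so
angle/distance oracles applied to the returned keypoints recover the
generating phenotype to machine precision.

Stimulus effects are additive offsets on the phenotype with the sign
structure the analyses must recover:

| field | sucrose | NaCl | bitterness | shock | water |
|---|---|---|---|---|---|
| ear_angle (deg) | +14 | +10 | −12 | −15 | 0 |
| whisker_angle (deg) | −9 | −6.5 | +9 | +11 | 0 |
| pupil_diameter (px) | +4 | +3.5 | +4 | +5 | 0 |

(remaining fields follow the same valence grouping; see
`synthgen.phenotype._DEFAULT_EFFECTS`). The published record for this
preparation reports directions and significance, not effect magnitudes, so
the defaults were chosen once for clear recoverability at realistic
noise levels and are not tuned per analysis.

Trial dynamics: each feature follows baseline → latency-delayed saturating
rise (time constant 0.15 s) toward baseline + offset during the 2 s
stimulus → exponential return (2 s). Latencies encode the empirical
ordering: whisker 0.1 s < ear/mouth/snout 0.3 s < pupil 1.0 s. Per-mouse
identity offsets are drawn once per animal (N(0, σ_field), σ_field ≈ 1–2 px
or deg); per-frame white noise defaults to half those dispersions. Sessions
run at 30 fps.

Photometry: the 470 nm channel is a decaying-exponential bleaching trend
plus a smooth motion artifact shared with the 410 nm channel, white noise,
and per-event transients (instant rise, 1.5 s decay) whose amplitudes
follow the recorded population — dopaminergic neurons prefer positive
valence (sucrose > NaCl > water > bitterness/shock), GABAergic the
reverse, glutamatergic arousal ({sucrose, shock} high), pan-neuronal flat.
Both channels sit on one 15 Hz clock; the hardware's interleaved
acquisition is not modeled.

All randomness flows from a single seed through one `SeedSequence`;
regeneration is bit-identical.

### What it does not emulate

No fur texture, lighting, or photorealistic appearance (the downstream
mathematics consumes edges and geometry, not realism); no licking
kinematics, blinks, or freely-moving pose variation; no tracking failures
beyond what tests inject synthetically. Passing tests therefore demonstrate
correctness of the *analysis machinery* and recoverability of *geometric
valence structure*, not performance on videographic mouse data.

## Appearance descriptors and prototypes

HOG: 8 orientation bins, 1×1 cells per block (block normalization
degenerates to per-cell L2 with a zero-guard), 16×16-px cells at the
1024-px reference input; `HOGConfig.for_canvas` scales the cell size with
the canvas so the descriptor stays 32 768-dimensional at every scale.

Apex/subprototype selection implements the two-step reading of "minimal
similarity to neutral, maximal similarity within stimulus": rank stimulus
frames by mean cosine similarity to the other stimulus frames, keep the top
10, then take the shortlist member(s) least similar to the neutral
baseline; ties break toward earlier frames. The simultaneous-optimization
reading is underdetermined and was rejected.

Prototypes average the subprototype HOG vectors within each valence
(positive ← sucrose, NaCl; negative ← bitterness, shock), built only from a
designated prototype mouse that is excluded from all evaluation. The
drug-session "normalized similarity difference" is not formula-defined in
the source material; it is implemented (in one isolated function) as the
baseline-z-scored epoch mean of `sim_pos − sim_neg`, with a flagged
unscaled fallback when the baseline variance is zero. Frames with exactly
zero difference are excluded from the positive/negative proportions
(measure-zero under floating point).

Unsupervised structure: PCA to 400 dimensions (clamped to the data), UMAP
with `n_neighbors = 45` (clamped) and `min_dist = 0.1`, then k-means on the
2-D UMAP coordinates (cluster centers live in the visualization plane); `k`
defaults to the number of stimulus conditions present. All stochastic steps
take explicit seeds.

## Coregistration

Six landmarks (nose tip, inner/outer eye corners, anterior lower-lip edge,
cheek, posterior pinna edge) anchor a least-squares affine fit, refined by
a restricted similarity transform computed in closed form
(orthogonal-Procrustes with scaling — the global optimum, so the refinement
can never be worse than the initialization's restriction). The unspecified
"contour similarity" term of the original procedure is not operationalized;
refinement minimizes landmark distances only. Warping uses inverse-mapped
bilinear interpolation with the frame median as fill; the schematic face
has no dedicated cheek keypoint, so the mouth-corner point (which lies on
the cheek margin) stands in.

## Kinematics

Keypoint QC follows the standard pose-estimation recipe: coordinates with
confidence < 0.9 are linearly interpolated between flanking confident
frames (edges held), then median-filtered over 5 frames. Geometry uses
image coordinates converted once to a y-up frame; directional angles
(ear vs +x, whisker vs −x) are folded into [0°, 180°] (signed variants are
available behind a flag); three-point angles are interior angles at the
middle vertex. The ear-angle vector originates at the ear-root keypoint.

Change scores: baseline = mean of the 4 s pre-stimulus window; change =
(value − baseline)/baseline; the "peak" is the signed extremum by absolute
value (a pure maximum would hide decreases). Water correction subtracts the
temporally nearest water trial's change per feature, ties toward the
earlier trial. Peak changes measured on raw noisy traces are biased upward
by the extremum operator; the documented pipeline (QC median filter first)
keeps the bias within the stated ±3-point recovery tolerance.

## Learned decoders

Because the deployment environment provides no deep-learning framework,
the decoders run on `faceval.nn`, a compact numpy layer library with
hand-written gradients (verified against finite differences). This also
makes Grad-CAM a plain backward pass rather than a framework hook.

Frame classifier: a reduced residual network — stride-2 stem convolution,
four residual blocks (8→8, 8→16/s2, 16→32/s2, 32→32/s1), global average
pooling, linear head — on 32-px inputs (64 px for saliency analyses, where
the final stride-1 block leaves an 8×8 conv grid for localization).
Optimizer: SGD with momentum 0.9 and L2 penalty 1e-4 (coefficient not
stated in the source; config-exposed), cross-entropy loss, 10 epochs,
batch 64, augmentation by random ±10° rotation and ±10% resize on the
training split only. The full-scale reference settings (50 epochs, batch
256, 224-px inputs, learning rate 0.001 on a pretrained 18-layer backbone)
are config-reachable but inappropriate at desk scale; the desk default
learning rate is 0.02. The shuffle control permutes training labels at the
frame level, which destroys every label-image association and pins
held-out accuracy at the 1/5 chance floor; trial-level permutation is
available but retains exploitable per-mouse structure and is not the
default control.

Siamese embedding: twin encoders realized as one batched pass through
shared layers; contrastive loss `1/(2N) Σ[y d² + (1−y) max(m−d,0)²]` with
the margin set to the mean interpair embedding distance at initialization
(the mean *squared* distance variant is behind a flag, since both
conventions circulate). Pairs follow the cross-mouse strategy — same
valence ⇒ different mice, different valence ⇒ same mouse, balanced 50/50,
neutral frames excluded — so identity is uninformative by construction and
generalization is evaluated on pairs from held-out mice.

Interpretability: class Grad-CAM weights last-conv activations by spatially
averaged gradients, rectifies, and normalizes each map to [0, 1];
similarity Grad-CAM backpropagates −d for same-valence and +d for
different-valence pairs through each branch (identical images, d = 0, give
a flagged zero map). Occlusion sensitivity fills region bounding-box masks
with the dataset mean gray value and retrains from scratch per region per
fold under stratified trial-level CV.

LSTM region decoder: per region, the four highest-variance keypoints'
(x, y) series over −0.5…+2 s are z-scored and downsampled by 3 to 25
timepoints (25 × 8 = 200 input dimensions), fed to a stacked LSTM
(desk default 128 units × 3 layers, half the reference width; dropout 0.3)
trained with Adam, ≤ 60 epochs with early stopping on the training loss
(the source is silent on LSTM optimization). Splits are always trial-level
and stratified; stratification requires every class in every fold and
errors otherwise.

## Photometry

airPLS: second-difference Whittaker smoother (λ = 1e8 at 15 Hz, max 50
iterations) with the standard exponential reweighting; points above the
running baseline get zero weight so positive transients are ignored.
Motion correction regresses the detrended 410 nm control onto the
detrended 470 nm signal over the full session (per-trial fitting is a
config option); ΔF/F = (signal − fitted control)/fitted control, with the
detrended channels re-anchored at the mean raw 470 level so the
denominator stays physiological. PSTHs subtract each trial's 4 s
pre-stimulus mean (baseline-window means are zero by construction); peak
ratios divide each stimulus's mean peak by the mean water peak.

The neural-facial correlation pools all samples in 2 s post-onset windows
on the shared 15 Hz clock (30 fps facial similarity is mapped down by
frame-pair averaging), computes Spearman's ρ, and tests it against a
within-window permutation null (circular shift available for
autocorrelation robustness) with the add-one one-sided p-value
`p = (1 + #{null ≥ obs}) / (1 + n_shuffles)`, which is valid by
construction and calibrated in the test suite. z-scoring is per session;
cross-session pooling is left to the caller.

## Pipeline

The `faceval` CLI wires the stages (synth → register → hog → prototype →
kinematics → decode → photometry → report) over a flat YAML config with
full-error-list validation. One global seed fans out to per-stage seeds by
hashing the stage name, so stages re-run independently yet reproducibly;
each stage writes a JSON provenance record.

## Problem sizes used in the checks

The test suite runs on cohorts of 3–5 mice with 1–4 trials per stimulus at
a 128-px canvas, and the benchmark chance-level computation uses 10 mice ×
5 trials per stimulus × 60 frames (15 000 frames) at 32-px classifier
input — sizes chosen so the full validation runs on a single CPU in
minutes while keeping every statistical check adequately powered. The
acceptance script averages three shuffle repetitions because a single
shuffled run's held-out accuracy moves in steps of whole test trials.

## Known limitations

- Schematic faces have step edges; HOG and saliency behave differently on
  fur texture, and interpolation-based oracles (e.g. warp round-trips) are
  stated for smooth images.
- The nose tip is placed relative to the lip to keep mouth inclination and
  snout–mouth length independently recoverable; real snouts do not move
  this way.
- Chance-level accuracy of a shuffled-label classifier is only tight when
  predictions decorrelate across trials; at very small cohort sizes the
  per-trial lumping widens its spread (documented in the test suite).
- The LSTM and occlusion analyses are desk-scaled; absolute accuracies are
  not comparable to full-scale recordings, only orderings and chance
  contrasts are.
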