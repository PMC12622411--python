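# faceval

Decoding emotional valence from the facial expressions of head-fixed mice.

Mice produce stereotyped, stimulus-specific facial movements: appetitive
tastants (sucrose, NaCl) raise the ears and protract the whiskers, while
aversive events (quinine-like bitterness, tail shock) fold the ears back,
retract the snout and squint — and the pupil dilates for any salient
stimulus. `faceval` is a reusable, tested implementation of a full analysis
stack for this problem, driven entirely by a synthetic-cohort generator so
every stage can be validated against exact ground truth:

- **`faceval.synthgen`** — schematic side-view mouse faces drawn from a
  ten-parameter geometric phenotype (ear angle/length/width/fold, whisker
  angle, mouth inclination, snout-mouth length, nose extension, pupil
  diameter, eye opening), with valence-structured stimulus effects,
  per-mouse identity offsets, response latencies, 30 fps trial dynamics and
  dual-channel (470/410 nm) fiber-photometry traces at 15 Hz.
- **`faceval.hogspace`** — Histogram-of-Oriented-Gradients frame
  descriptors (8 orientation bins, 16×16-px cells at the 1024-px reference
  scale, per-cell L2 normalization), cosine similarity
  `cos(a,b) = a·b / (‖a‖‖b‖)`, motion energy, two-step apex-frame
  selection, and PCA → UMAP → k-means embedding of expression space.
- **`faceval.register`** — six-landmark affine + similarity coregistration
  of faces across mice, with red/cyan QC overlays.
- **`faceval.prototype`** — positive/negative valence prototypes (averaged
  subprototype HOG vectors from a designated, held-out prototype mouse),
  per-frame prototype-similarity timecourses, cumulative similarities, and
  the drug-session valence index (baseline-z-scored similarity difference,
  positive/negative frame proportions).
- **`faceval.kinematics`** — keypoint QC (confidence filtering, linear
  interpolation, 5-frame median smoothing), the ten-feature facial geometry
  battery over 37 tracked keypoints, baseline-relative proportional change
  scores with water-control correction, keypoint PCA and response latencies.
- **`faceval.decoders`** — a reduced residual frame classifier with
  label-shuffle control, a Siamese contrastive embedding trained with the
  cross-mouse pair strategy (same-valence pairs span different mice;
  different-valence pairs come from one mouse), Grad-CAM class and
  similarity saliency maps, occlusion-sensitivity analysis with per-region
  retraining under trial-level cross-validation, and region-wise LSTM
  decoding of keypoint trajectories (25 timepoints × 8 channels = 200-D).
- **`faceval.photometry`** — airPLS baseline removal, isosbestic motion
  correction (`ΔF/F = (signal − fitted control)/fitted control`),
  event-aligned PSTHs with 4 s baselines, water-normalized peak ratios, and
  the permutation-tested Spearman correlation between neural activity and
  facial valence similarity.
- **`faceval.nn`** — the compact numpy neural-network core behind the
  decoders (strided convolutions, batch norm, residual blocks, LSTM,
  contrastive loss `L = 1/2N Σ[y·d² + (1−y)·max(m−d, 0)²]`), written with
  explicit forward/backward passes so saliency analyses are first-class.

The two pairwise objectives above use the field's standard notation: `d` is
the Euclidean distance between twin-branch embeddings, `y = 1` for
same-valence pairs, and the margin `m` defaults to the mean interpair
distance of the training set.

## Worked example

Build a small cohort, score a held-out mouse against valence prototypes,
and check that the valence readout has the right sign:

```python
import numpy as np
from faceval.synthgen import SyntheticCohortSpec, ValenceEffectSpec, build_cohort
from faceval.hogspace import HOGConfig, hog_matrix
from faceval.prototype import select_subprototypes, build_prototype, score_stream

spec = SyntheticCohortSpec(n_mice=2, trials_per_stimulus=1, frame_size=128,
                           seed=11, pre_window_s=1.0, post_window_s=1.0)
eff = ValenceEffectSpec(frame_noise=0.0)
eff.latency_s = {k: 0.0 for k in eff.latency_s}
cohort = build_cohort(spec, eff)

cfg = HOGConfig.for_canvas(128)
sub = {}
for seg in cohort[0].trials:          # mouse m00 is the prototype source
    hogs, _ = hog_matrix(seg.frames, cfg)
    stim = (seg.times >= 0) & (seg.times < seg.duration_s)
    if seg.stimulus == "water":
        neutral = hogs[~stim]
    else:
        sub[seg.stimulus] = (hogs[stim], None)
sub = {s: h[select_subprototypes(h, neutral, k=5)] for s, (h, _) in sub.items()}
proto = build_prototype(sub, source_mouse="m00")

for stimulus in ("sucrose", "shock"):
    seg = next(t for t in cohort[1].trials if t.stimulus == stimulus)
    hogs, _ = hog_matrix(seg.frames, cfg)
    tc = score_stream(hogs[(seg.times >= 0) & (seg.times < 2.0)], proto)
    print(f"{stimulus:8s} mean(sim_pos - sim_neg) = {tc.diff.mean():+.4f}")
```

Output:

```
sucrose  mean(sim_pos - sim_neg) = +0.3170
shock    mean(sim_pos - sim_neg) = -0.3100
```

A positive difference means the held-out mouse's sucrose expression
resembles the positive prototype built from a *different* mouse more than
the negative one — the cross-animal generalization at the heart of the
prototype approach — and the shock trial lands on the negative side.

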