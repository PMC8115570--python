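# Methods

This note documents the models, defaults and numerical choices behind
`gazevam`, and what the synthetic experiments do and do not establish.

## Pipeline model

The package learns one visual attention model (VAM) per subject group from
pooled gaze over a two-panel video, then classifies individuals by
per-frame map-matching votes. The stages and their contracts are described
in the module docstrings; this note concentrates on the choices that were
genuinely open.

### Coordinate and resolution conventions

* Preprocessed frames are 200 rows × 350 columns (70,000 pixels),
  preserving the landscape aspect of the 1920×1080 source (1.75 vs 1.78).
  All per-pixel quantities (motion normalization, match similarity) are
  normalized by the actual pixel count `frame.size`.
* Coordinates are 0-based `(row, col)` with half-open pixel bins; gaze is
  binned by flooring after the affine crop+resize transform. A sample is
  assigned to the frame whose display interval `[t_i, t_i + 1/fps)`
  contains its timestamp; samples on removed transition frames are dropped.
* Downscaling uses area (block-average) interpolation
  (`skimage.transform.resize_local_mean`): it is anti-aliasing and exactly
  mean-preserving, which the feature channels and the checkerboard
  regression test rely on.
* The border threshold for "black" is intensity < 0.02 in all channels,
  robust to video-compression noise.

### Frame aggregation

The per-pixel motion estimator defaults to the absolute temporal intensity
difference of frames scaled to [0, 1] — already normalized, linear in the
temporal difference, and the quantity the aggregation rule's description
emphasizes. A dense optical-flow magnitude estimator
(`skimage.registration.optical_flow_ilk`, clipped and normalized by a
configured maximum displacement) is available behind the same contract.
The greedy rule compares the *running mean frame* of the open set against
the next frame (not the last member), and the 0.33 threshold is config: it
is a property of the stimulus video and should be re-examined for any other
stimulus. Where the frame sequence is not temporally contiguous (segment
changes, held-out diagnosis frames, removed transitions) the pipeline
forces set boundaries, so no set straddles a discontinuity or a side swap.

### Fixation maps and coordinate selection

Group maps are raw landing counts smoothed with a unit-sum 5×5 Gaussian,
sigma 1 px (the kernel size is fixed by the method; sigma was unspecified
and is config), zero-padded at the boundary so interior mass is conserved.
Class-1 coordinates are the top-350 cells with the deterministic tie-break
(value desc, row asc, col asc); class-0 cells are drawn uniformly, seeded,
from exactly-zero cells — deliberately *not* excluding the neighbourhood of
class-1 cells, since smoothing already lifts near-fixation zeros to small
positive values.

### Feature bank

28 channels in a frozen registry order (steerable ×13, conspicuity ×4,
RGB ×3, semantic ×3, geometry ×4, motion ×1).

* Steerable subbands are second-derivative-of-Gaussian steerable filters
  (σ = 1.2 px, 9×9 kernels) at edge orientations {0°, 60°, 120°} on a
  4-level Gaussian pyramid, magnitudes upsampled to frame size; the 13th
  channel is the low-pass residual — the only consistent reading of "13
  channels with four scales and three orientations".
* Conspicuity maps follow the center-surround architecture: Gaussian
  pyramid levels c ∈ {1, 2} vs surrounds c+{2, 3}, absolute differences
  summed across scales, for intensity and for the R−G / B−(R+G)/2 opponent
  channels; orientation conspicuity is the summed oriented-energy of the
  steerable subbands; skin is a normalized-rg chrominance likelihood
  (locus (0.45, 0.31), σ 0.06), an analytic [0, 1] map that is *not*
  re-scaled per frame.
* Structure channels (steerable, color/intensity/orientation conspicuity)
  are min-max scaled per frame; RGB, distances and flags have fixed
  analytic ranges. Distances are normalized by the distance from the
  (frame or half-screen scene) center to its farthest corner. "Scene
  center" means the geometric center of the half-screen, not of the moving
  content.
* Semantic channels take oracle masks when available (synthetic runs are
  then exactly deterministic); otherwise registered detectors. The default
  detectors are simple heuristics (skin-blob face scorer, skin+motion
  people scorer, dominant-gradient-band horizon scorer) intended as
  baselines for real footage and replaceable per channel.

### Feature selection

The GA is a generational wrapper: binary masks over the 28 channels,
tournament selection (size 3), one-point crossover (0.8), bit-flip mutation
(1/28), elitism 1, population 40 × 50 generations; empty masks are
repaired. Fitness is injectable; the default is 3-fold CV AUC of the
downstream network at reduced epochs. The reference subset size of 15 is
honored as a post-search constraint: when the best mask's cardinality
differs, genes are re-ranked by fitness-weighted frequency in the final
population (ties: membership in the best mask, then index) and the mask is
resized exactly. Both modes — free cardinality and fixed target — are
exposed because the reference protocol is compatible with either reading.
Relief is the classic binary variant (features scaled to [0, 1], nearest
hit/miss differences), provided as the filter alternative.

### The VAM network

10 sigmoid hidden units, one linear output unit; per-sample SGD on binary
cross-entropy with learning rate 0.01, at most 1000 epochs or mean epoch
loss < 1e-7 (the tolerance is interpreted on the *mean epoch* loss and is
config). A linear output paired with cross-entropy is read as
logits-with-BCE: the logistic link is applied inside the loss and at
prediction — the only numerically coherent interpretation, applied
consistently. Per-feature min-max normalization is fitted on the training
vectors and stored with the model. Weights initialize uniform(−0.5, 0.5)
from the seeded generator; training is bit-reproducible for a fixed seed.
Saliency maps threshold the predicted probability at 0.5, the boundary
counting as fixated.

### Diagnosis

Match similarity is the count of positions where the binary fixation and
saliency maps agree. Votes go to the strictly more similar group; exact
ties resolve to the control group (conservative with respect to a
case diagnosis). The ROC sweeps every integer vote threshold (0..F+1 so
both endpoints are present) and integrates by trapezoid over (FPR, TPR)
sorted lexicographically — equivalent to the Mann–Whitney U statistic with
tie credit, which the tests verify. Youden's J maximizer breaks ties toward
the smallest threshold. Cross-validation is subject-wise and stratified;
the per-fold threshold is chosen on the test fold's ROC (the reference
protocol, optimistic by construction) with an honest nested variant —
threshold from the training subjects' ROC — behind
`threshold_mode="train"`.

**Foveal extent in the individual maps.** A raw gaze sample marks a single
pixel, but the fovea covers ≈1° of visual angle — about 8 px on the 200×350
grid at typical viewing distance. In the diagnosis phase the subject's
per-frame hit map is therefore dilated by a disk of radius 8 px
(`dilation_radius`, config; the bare `individual_fixation_map` operation
defaults to radius 0). This matters structurally: with single-pixel hits
(~10–30 per frame against 70,000-pixel maps), the match count is dominated
by the two saliency maps' *area difference*, which is identical for every
subject within a fold — vote counts then carry no between-subject
information at all and the classifier is pinned at chance regardless of
cohort size. Marking the foveal neighbourhood restores the comparison the
vote is meant to make. Radius 0 reproduces the literal binarized-hits rule.

## Synthetic data: what it emulates and what it does not

The generator renders a 9-segment, 6-s-per-segment, two-panel stimulus at
270×480 with a black margin (quarter of the original display's resolution,
same 16:9 aspect — preprocessing resizes to 200×350 regardless, so render
scale only bounds memory) at 10 fps: textured moving ellipse "people" with
a bright face disc on the biological half, rotating polygons over texture
on the geometric half, sides alternating per segment, all content re-drawn
per segment. Both halves are textured because the clinical stimuli are rich
video on both sides; a flat background on one half makes that half's
learned saliency map systematically smaller — an artifact of the proxy, not
of the paradigm. Per-frame oracle masks (face, person,
biological/geometric region) feed the semantic channels and the gaze
simulator.

Gaze is simulated at 300 Hz (the reference tracker's rate) as: choose the
geometric half with probability `p_geometric`; within the chosen half emit
uniform noise with probability 0.05, otherwise a Gaussian (σ 40 px) around
the face centroid (biological half, probability `face_attraction`) or the
half's center, clipped to the half; drop each tick with `dropout_rate`
(0.05). The reference phenotypes differ **only** in `p_geometric` (0.8
case vs 0.2 control), keeping the within-half gaze structure
mirror-symmetric between groups.

Not modeled: saccade dynamics and fixation physiology, photorealistic
content, tracker calibration drift, and any within-group clinical
heterogeneity. Passing the parameter-recovery tests therefore shows that
the pipeline's inference machinery recovers a known side-preference
contrast through the full learning+voting path; it does not validate
clinical performance on real recordings, whose group differences are far
subtler.

## Problem sizes and numerical notes

The reference synthetic study runs the full 9-segment stimulus, 20
subjects per group, 50 held-out diagnosis frames, 5 folds; training uses up
to 10 frame sets per fold (evenly subsampled; `max_framesets`) and 150 SGD
epochs — the pixel task converges well before that, and these sizes keep a
full two-condition study in the minutes range on one core. Frame sets whose
fixation map cannot supply 350 nonzero or 350 zero cells (very short sets
under sparse gaze) are skipped with a count recorded; at least one must
survive per group or training errors out. Feature stacks are float32 and
streamed: per-frame stacks accumulate directly into frame-set means, so
memory stays at tens of stacks rather than hundreds.

Known limitations: the voting channel discards the match-count magnitudes
(a margin-based classifier would use strictly more information); the
test-fold Youden threshold inflates the operating-point metrics (use
`threshold_mode="train"` for honest ones; AUC is unaffected); and the GA
wrapper's fitness at full network cost is expensive — the default
cross-validation path trains on all 28 channels, with selection exposed as
a separate, pluggable step.
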