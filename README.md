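# gazevam

Group-level **visual attention models (VAMs)** from eye-tracking data over
video stimuli, and a saliency-map voting classifier built on them.

## The problem

In the preferential-looking paradigm for autism research, a screen is split
into two panels — biological motion (children interacting, faces) on one
side, geometric/fractal motion on the other — and where a child looks is
diagnostic: case-group children spend more time on the geometric half and
less on faces. Classic analyses hand-draw regions of interest on every
frame and compare dwell times. This package implements the ROI-free
alternative: *learn* each group's visual attention from its pooled gaze,
then classify an individual by which group's learned attention pattern their
own gaze matches better.

## The method

Two phases over a stimulus video and per-subject gaze streams
(timestamp + screen x,y):

**VAM learning** — per group (case, control):

1. *Preprocess*: crop the black border, resize frames to 200×350, drop the
   10 frames on each side of every segment boundary; map gaze through the
   same transform.
2. *Aggregate*: merge consecutive frames while the mean motion between the
   running mean frame and the next frame is < 0.33 (mean over pixels of the
   normalized per-pixel motion magnitude); pool each set's gaze.
3. *Fixation maps*: per frame set, accumulate the group's gaze into pixel
   counts and smooth with a 5×5 Gaussian.
4. *Coordinates*: the 350 highest cells → class 1 (fixated); 350 random
   zero cells → class 0, i.e. 700 balanced coordinates per map.
5. *Features*: a 28-channel per-pixel bank — 13 steerable-pyramid maps
   (4 scales × 3 orientations + low-pass), 4 conspicuity maps (color,
   intensity, orientation, skin), RGB, 3 semantic maps (horizon, face,
   people; oracle masks or pluggable detectors), distance to frame/scene
   center, the biological/geometric scene flags, and motion. Frame-set
   features are the mean over member frames. A genetic-algorithm wrapper
   (Relief as the filter alternative) can reduce the 28 channels to 15.
6. *Train*: a network with one hidden layer of 10 sigmoid units and a
   linear output read through a logistic link, per-sample SGD on binary
   cross-entropy (lr 0.01, ≤1000 epochs or mean epoch loss < 1e-7),
   predicting P(pixel fixated | features).

**Diagnosis** — for an individual on held-out frames: threshold each VAM's
per-pixel prediction at 0.5 into two binary saliency maps per frame; build
the subject's binary fixation map for the frame; count positions where the
maps agree (the match similarity); the more similar group earns the frame's
vote. Sweeping the case-vote threshold over all integers yields a ROC; the
Youden index J = sensitivity + specificity − 1 picks the operating
threshold. Evaluation is subject-wise stratified 5-fold cross-validation
with 50 diagnosis frames held out of VAM learning.

Clinical gaze recordings are not distributable, so the package ships a
first-class synthetic module: a two-panel proxy stimulus with per-frame
oracle masks, and a gaze simulator whose phenotype parameters
(`p_geometric`, center bias, face attraction, dropout) generate
group-conditional streams. Everything downstream is testable end to end
against known ground truth.

## Worked example

```python
from gazevam.pipeline import run_synthetic_crossval
import gazevam as gv
from gazevam.vam import TrainConfig

manifest = gv.default_manifest(n_segments=3, segment_seconds=3.0, fps=10.0,
                               screen_size=(135, 240))
report = run_synthetic_crossval(n_per_group=6, manifest=manifest,
                                n_diag_frames=10, k=3, seed=0,
                                train_cfg=TrainConfig(max_epochs=60, seed=0))
print(report.summary())
```

prints (examples/07_crossval_diagnosis.py):

```
mean AUC over folds: 1.000 (pooled 1.000)
precision 1.00  sensitivity 1.00 specificity 1.00
per-fold Youden vote thresholds (of 10 frames): [1, 1, 1]
  fold 0: labels [1, 1, 0, 0] case-votes [7, 6, 0, 0]
  fold 1: labels [1, 1, 0, 0] case-votes [10, 10, 0, 0]
  fold 2: labels [1, 1, 0, 0] case-votes [10, 10, 0, 0]
```

Case subjects (simulated geometric-side preference 0.8) collect 6–10 case
votes out of 10 diagnosis frames; controls (preference 0.2) collect 0: the
learned VAMs recover the simulated phenotype contrast perfectly and the
Youden threshold separates the two vote distributions. The `examples/`
directory has one short script per capability (stimulus generation,
preprocessing and aggregation, fixation maps, the feature bank, GA/Relief
selection, VAM training, cross-validated diagnosis).

A thin CLI wraps the same pipeline:
`gazevam simulate | preprocess | train | diagnose | crossval` (see
`gazevam --help`).

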