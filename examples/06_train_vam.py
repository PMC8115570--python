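"""Train one group's visual attention model and emit a binary saliency map.

The VAM is a 10-hidden-unit network over per-pixel feature vectors; applied
to every pixel of a frame's stack and thresholded at 0.5 it predicts which
pixels that group would fixate.
"""

import numpy as np

import gazevam as gv
from gazevam.diagnosis import train_group_vam
from gazevam.pipeline import prepare_stimulus, simulate_cohort
from gazevam.vam import TrainConfig, binary_saliency_map

manifest = gv.default_manifest(n_segments=3, segment_seconds=3.0, fps=10.0,
                               screen_size=(135, 240))
frames, masks = gv.generate_stimulus(manifest, seed=0)
bundle = prepare_stimulus(frames, manifest, masks, n_diag_frames=4, seed=0)
streams, labels = simulate_cohort(bundle, manifest, masks["face"],
                                  n_per_group=4, seed=0)

case_streams = [streams[s] for s in streams if labels[s] == "case"]
model, used, skipped = train_group_vam(
    case_streams, bundle.framesets, bundle.frameset_stacks,
    TrainConfig(max_epochs=60, seed=0), seed=0, n_pos=350, n_neg=350,
    feature_indices=None, group="case")
print(f"trained on {used} frame sets ({skipped} skipped), "
      f"{model.epochs_run} epochs, final loss {model.final_loss:.3f}")

sal = binary_saliency_map(model, bundle.diag_stacks[0])
geo = bundle.diag_stacks[0]["flag_geometric"] > 0.5
print(f"saliency map: {sal.mean():.0%} of pixels predicted fixated; "
      f"{sal[geo].mean():.0%} of the geometric half vs {sal[~geo].mean():.0%} "
      f"of the biological half")
# A case-group model (geometric-preferring phenotype) should predict far
# more fixations on the geometric half.
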