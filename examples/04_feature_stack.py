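"""Extract the 28 per-pixel feature channels for one frame.

Channels cover bottom-up structure (13 steerable-pyramid maps, 4 Itti-style
conspicuity maps, RGB), semantics (horizon/face/people score maps — here
exact oracle masks), geometry (distances to frame and scene centers, the two
scene-type flags) and motion against the previous frame.
"""

import numpy as np

import gazevam as gv
from gazevam.features import extract_feature_stack, FrameContext
from gazevam.preprocess import preprocess_frames

manifest = gv.default_manifest(n_segments=2, segment_seconds=3.0, fps=10.0,
                               screen_size=(135, 240))
frames, masks = gv.generate_stimulus(manifest, seed=0)
seq, small_masks, _ = preprocess_frames(frames, manifest, masks)

ctx = FrameContext(bio_side=seq.manifest.side_of_frame(1),
                   prev_frame=seq.frames[0],
                   masks={k: v[1] for k, v in small_masks.items()})
stack = extract_feature_stack(seq.frames[1], ctx)

print(f"stack: {stack.channels.shape[0]} channels of "
      f"{stack.channels.shape[1]}x{stack.channels.shape[2]}")
for name in stack.channel_names:
    ch = stack[name]
    print(f"  {name:28s} range [{ch.min():.2f}, {ch.max():.2f}] mean {ch.mean():.3f}")
# Flag channels are exactly 0/1, semantic channels copy the oracle masks,
# and every structure channel is scaled to [0, 1] within the frame.
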