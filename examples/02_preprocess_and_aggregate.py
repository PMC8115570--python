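"""Preprocess a stimulus and group its frames by motion.

Preprocessing crops the black border, resizes every frame to 200x350 and
drops 10 frames on each side of every segment boundary. Aggregation then
merges consecutive frames while the mean motion between the running mean
frame and the next frame stays below 0.33 — pooling gaze over near-static
intervals so fixation maps are dense enough to learn from.
"""

import gazevam as gv
from gazevam.aggregation import aggregate_frames
from gazevam.preprocess import preprocess_frames

manifest = gv.default_manifest(n_segments=3, segment_seconds=3.0, fps=10.0,
                               screen_size=(135, 240))
frames, masks = gv.generate_stimulus(manifest, seed=0)
seq, small_masks, box = preprocess_frames(frames, manifest, masks)

print(f"raw frames: {len(frames)}  crop box: {box}")
print(f"preprocessed: {seq.count} frames of {seq.frame_shape[0]}x{seq.frame_shape[1]} "
      f"({len(frames) - seq.count} transition frames removed)")

sets = aggregate_frames(seq)
sizes = [len(s) for s in sets]
print(f"aggregation: {len(sets)} frame sets, sizes {sizes}")
print(f"  (each set's mean frame and pooled gaze form one training unit)")
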