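"""Render a small two-panel stimulus video with its oracle masks.

The screen is split into a biological half (moving textured "people" with a
bright face disc) and a geometric half (rotating polygons); the sides swap
between segments. The masks tell downstream code exactly where the faces,
people and each motion type are — ground truth a real experiment would get
from annotation or detectors.
"""

import gazevam as gv

manifest = gv.default_manifest(n_segments=3, segment_seconds=3.0, fps=10.0,
                               screen_size=(135, 240))
frames, masks = gv.generate_stimulus(manifest, seed=0)

print(f"segments: {len(manifest.segments)}, frames: {frames.shape[0]}, "
      f"screen: {frames.shape[1]}x{frames.shape[2]}")
for i, seg in enumerate(manifest.segments):
    print(f"  segment {i}: frames [{seg.start}, {seg.end}), "
          f"biological side = {seg.biological_side}")
face_px = masks["face"][0].sum()
print(f"frame 0: {face_px} face-mask pixels, "
      f"{masks['biological'][0].mean():.0%} of the screen is biological")
# The face occupies a small patch inside the biological half; the two motion
# masks partition the content area.
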