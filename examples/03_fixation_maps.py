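"""Build a group fixation map and pick balanced training coordinates.

Gaze samples from every subject of a group are accumulated per frame set
into pixel counts and smoothed with a 5x5 Gaussian. The 350 highest cells
become class-1 (fixated) training coordinates; 350 random zero cells become
class-0 — 700 balanced coordinates per map.
"""

import gazevam as gv
from gazevam.aggregation import aggregate_frames, aggregate_gaze
from gazevam.fixation import group_fixation_map, select_coordinates
from gazevam.pipeline import map_subject, prepare_stimulus

manifest = gv.default_manifest(n_segments=3, segment_seconds=3.0, fps=10.0,
                               screen_size=(135, 240))
frames, masks = gv.generate_stimulus(manifest, seed=0)
bundle = prepare_stimulus(frames, manifest, masks, n_diag_frames=0, seed=0)

params = gv.PhenotypeParams(p_geometric=0.8, seed=1)
streams = []
for i in range(4):
    import dataclasses
    df = gv.generate_gaze(manifest, dataclasses.replace(params, seed=i),
                          face_masks=masks["face"], subject_id=f"S{i}")
    streams.append(map_subject(bundle, df))

per_set = aggregate_gaze(streams, bundle.framesets)
fmap = group_fixation_map(per_set[0], frameset_id=0, group="case")
print(f"frame set 0: {int(fmap.raw_counts.sum())} pooled samples from 4 subjects")
print(f"  nonzero cells after smoothing: {(fmap.counts > 0).sum()} of 70000")

sample = select_coordinates(fmap, seed=0)
print(f"selected {len(sample.coords)} coordinates "
      f"({sample.n_pos} fixated + {sample.n_neg} non-fixated)")
# These coordinates index the frame set's mean feature stack to produce the
# labeled pixel vectors the group's attention model trains on.
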