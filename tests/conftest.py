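"""Shared fixtures: a small synthetic stimulus and cohort, built once."""

import numpy as np
import pytest

import gazevam as gv
from gazevam.pipeline import prepare_stimulus, simulate_cohort


@pytest.fixture(scope="session")
def tiny_manifest():
    # 3 segments x 3 s at 10 fps: long enough to survive transition removal
    return gv.default_manifest(n_segments=3, segment_seconds=3.0, fps=10.0,
                               screen_size=(135, 240))


@pytest.fixture(scope="session")
def tiny_stimulus(tiny_manifest):
    frames, masks = gv.generate_stimulus(tiny_manifest, seed=7)
    return frames, masks


@pytest.fixture(scope="session")
def tiny_bundle(tiny_manifest, tiny_stimulus):
    frames, masks = tiny_stimulus
    return prepare_stimulus(frames, tiny_manifest, masks,
                            n_diag_frames=6, seed=7, max_framesets=6)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_bundle, tiny_manifest, tiny_stimulus):
    _, masks = tiny_stimulus
    streams, labels = simulate_cohort(tiny_bundle, tiny_manifest, masks["face"],
                                      n_per_group=6, seed=7)
    return streams, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
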