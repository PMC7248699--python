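"""Shared fixtures: a small synthetic dataset and a tiny network.

Scaled for speed (3 subjects x 3 activities, 3-second streams, 32-px canvas)
while keeping every pipeline stage non-degenerate: multiple subjects and
activities so every negative type exists, and more than one clip per stream
so disjoint-window negatives exist.
"""

import numpy as np
import pytest

from simatch.encoders import ArchConfig, build_model
from simatch.preprocess import PreprocConfig, clips_from_streams
from simatch.synthdata import SynthConfig, gen_streams

TINY_SYNTH = SynthConfig(n_subjects=3, duration_s=3.0, canvas=(48, 48), seed=123)
TINY_PREPROC = PreprocConfig(clip_len=30, overlap=0.5, target_size=32)
TINY_ARCH = ArchConfig(channels=(4, 8, 16), embed_dim=16, dropout_rate=0.0)


@pytest.fixture(scope="session")
def tiny_streams():
    return gen_streams(TINY_SYNTH)


@pytest.fixture(scope="session")
def tiny_clips(tiny_streams):
    return clips_from_streams(tiny_streams, TINY_PREPROC)


@pytest.fixture(scope="session")
def tiny_net(tiny_clips):
    return build_model(TINY_ARCH, np.random.default_rng(0), input_shape=tiny_clips[0].sil.shape)
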