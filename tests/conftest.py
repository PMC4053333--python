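from __future__ import annotations

import numpy as np
import pytest

from camtriage import LabeledRecording, VideoTensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tensor(rng, t=6, h=8, w=8, frame_period=1.0):
    return VideoTensor(
        frames=rng.random((t, h, w)), frame_period=frame_period, source_id="rand"
    )


@pytest.fixture
def random_tensor(rng):
    return make_tensor(rng)


def make_recordings(target_d, nontarget_d, method="filter1", condition="unknown"):
    """Build LabeledRecording lists from plain D-value sequences."""
    recs = []
    for i, d in enumerate(target_d):
        recs.append(
            LabeledRecording(
                source_id=f"t{i}", d_values={method: float(d)}, label="target",
                condition=condition,
            )
        )
    for i, d in enumerate(nontarget_d):
        recs.append(
            LabeledRecording(
                source_id=f"n{i}", d_values={method: float(d)}, label="non-target",
                condition=condition,
            )
        )
    return recs
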