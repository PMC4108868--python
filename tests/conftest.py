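import numpy as np
import pytest

import halometry as h


@pytest.fixture(scope="session")
def study_layout():
    """The reference 72-stimulus layout (18 semiaxes x 4 rings, max 60 px)."""
    return h.generate_layout(None)


@pytest.fixture(scope="session")
def study_schedule(study_layout):
    return h.build_schedule(study_layout, seed=12345)


def matrix_with_misses(layout, misses):
    """Detection matrix over a layout with given per-stimulus miss counts."""
    p = layout.config.weight
    return h.DetectionMatrix(
        stimulus_ids=layout.stimulus_ids,
        presentations=np.full(layout.n_stimuli, p),
        misses=np.asarray(misses, dtype=int),
    )
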