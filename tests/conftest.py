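import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from spineburst import synth


@pytest.fixture(scope="session")
def small_stack_series():
    """One noise-free, drift-free imaging session (small frames)."""
    params = synth.SpineSimParams(
        frame_shape=(128, 128, 8), n_spines=3, shot_noise=False, jitter_px=0,
        bleach_per_timepoint=0.0, seed=11,
    )
    return synth.gen_spine_stack_series(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
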