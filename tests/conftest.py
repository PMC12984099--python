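import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from imflight.phantoms import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """A 64x64 phantom spec with layer scales shrunk to fit the canvas."""
    return PhantomSpec(
        height=64, width=64, illum_scale=48.0, vessel_width=2.5,
        lesion_radius_range=(3.0, 6.0), seed=11,
    )


@pytest.fixture
def tiny_spec():
    """A 16x16 spec for fast classifier plumbing tests."""
    return PhantomSpec(
        height=16, width=16, illum_scale=12.0, vessel_width=1.5,
        n_vessels=2, lesion_radius_range=(1.0, 2.0), seed=3,
    )
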