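import math

import numpy as np
import pytest

from spooltrace.spiral import SpiralSpec, make_multi_entry
from spooltrace.density import synth_map


@pytest.fixture(scope="session")
def cyl_spec():
    """Small cylindrical multi-start spec used across density/scan tests."""
    return SpiralSpec(
        geometry="cylindrical", r=10.0, p=25.0, phi0=math.radians(40.0),
        h=8.0, n_entries=4,
    )


@pytest.fixture(scope="session")
def cyl_map(cyl_spec):
    """Noise-free planted map for cyl_spec."""
    trace = make_multi_entry(cyl_spec)
    return synth_map(trace, sigma=0.5, voxel=0.4, padding=2.0)


def random_axis(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
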