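import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from avcalc.phantoms import PhantomSpec, CalcBlob, generate
from avcalc.volume import ImageVolume


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def iso_grid():
    """64-cube 1 mm grid for geometry tests."""
    return ImageVolume(np.zeros((64, 64, 64), dtype=np.float32), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def plain_phantom():
    """Default phantom, no calcium."""
    return generate(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def calc_phantom():
    """Phantom with two inside calcifications and one distractor."""
    base = generate(PhantomSpec(seed=11))
    p = base.params
    inside1 = p.origin_mm + np.array([5.0, 0.0, -4.0])
    inside2 = p.origin_mm + np.array([-6.0, 4.0, 6.0])
    outside = p.origin_mm + np.array([21.0, 21.0, 0.0])  # ~30 mm radial, off-grid-safe
    spec = PhantomSpec(
        seed=11,
        cylinder=p,
        blobs=[
            CalcBlob(center_mm=tuple(inside1), radius_mm=3.0, peak_hu=600.0),
            CalcBlob(center_mm=tuple(inside2), radius_mm=2.0, peak_hu=300.0),
            CalcBlob(center_mm=tuple(outside), radius_mm=3.0, peak_hu=800.0, inside=False),
        ],
    )
    return generate(spec)
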