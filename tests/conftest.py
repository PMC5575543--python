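import numpy as np
import pytest
from scipy import ndimage

from petbench.core_io import ImageVolume, VoiMask
from petbench.simulator import PhantomSpec, TumorSpec, build_phantom


def random_mask_pair(rng, shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0),
                     origin=(0.0, 0.0, 0.0)):
    """Two overlapping blobby non-empty masks on a shared small grid."""
    while True:
        field = ndimage.gaussian_filter(rng.random(shape), 1.2)
        a = field > np.quantile(field, 0.75)
        shift = rng.integers(-2, 3, size=3)
        b = np.roll(a, shift, axis=(0, 1, 2))
        # roll wraps around; mask out the wrapped margin to keep b simple
        noise = ndimage.gaussian_filter(rng.random(shape), 1.2)
        b = b ^ (noise > np.quantile(noise, 0.9))
        if a.any() and b.any():
            ma = VoiMask(a, spacing, origin, "f", "A")
            mb = VoiMask(b, spacing, origin, "f", "B")
            return ma, mb


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def two_level_phantom():
    """Noiseless two-valued image: a 10 mm sphere of uptake 10 on background 1."""
    spec = PhantomSpec((40, 40, 24), (2.0, 2.0, 2.0),
                       [TumorSpec((40.0, 40.0, 24.0), 10.0, 10.0)],
                       background=1.0)
    image, rcs = build_phantom(spec)
    return image, rcs[0]


@pytest.fixture
def hn_reference_contour():
    """An H&N-like ellipsoidal reference contour on a 2 mm grid."""
    spec = PhantomSpec((64, 64, 40), (2.0, 2.0, 2.0),
                       [TumorSpec((64.0, 64.0, 40.0), (15.0, 12.0, 10.0), 6.0,
                                  shape="ellipsoid", label="hn")],
                       background=1.0)
    image, rcs = build_phantom(spec)
    return image, rcs[0]


def make_image(voxels, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
               frame="f"):
    return ImageVolume(np.asarray(voxels, dtype=float), spacing, origin, frame)


def make_mask(bits, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
              frame="f", label=""):
    return VoiMask(np.asarray(bits, dtype=bool), spacing, origin, frame, label)
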