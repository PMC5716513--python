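import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spectplan.imaging_core import LabelMask, Volume
from spectplan.phantom import (PhantomSpec, default_pose, generate_ct_phantom,
                               generate_spect_phantom)

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

#: Reduced-anatomy phantoms keep the unit tests fast; the acceptance suite
#: exercises the full default geometry.
SMALL = dict(ct_shape=(72, 72, 48), ct_spacing=(3.0, 3.0, 3.0),
             organ_scale=0.8)
TINY = dict(ct_shape=(48, 48, 32), ct_spacing=(4.0, 4.0, 4.0),
            organ_scale=0.55)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(**SMALL)


@pytest.fixture(scope="session")
def tiny_spec():
    return PhantomSpec(**TINY)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_ct_phantom(small_spec, seed=11)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_spec):
    return generate_ct_phantom(tiny_spec, seed=11)


@pytest.fixture(scope="session")
def small_spect_pair(small_spec, small_phantom):
    """Liver mask, known CT->SPECT pose, and the SPECT volume acquired at it."""
    _, masks = small_phantom
    pose = default_pose(masks["liver"])
    spect = generate_spect_phantom(masks["liver"], pose, small_spec, seed=12)
    return masks["liver"], pose, spect


def make_sphere_mask(radius_mm=20.0, spacing=(2.0, 2.0, 2.0), margin_mm=8.0,
                     center_offset=(0.0, 0.0, 0.0)):
    spacing = np.asarray(spacing, dtype=float)
    half = radius_mm + margin_mm
    shape = (np.ceil(2 * half / spacing)).astype(int) + 1
    ax = [np.arange(n) * s - (n - 1) * s / 2.0
          for n, s in zip(shape, spacing)]
    r2 = ((ax[0][:, None, None] - center_offset[0]) ** 2
          + (ax[1][None, :, None] - center_offset[1]) ** 2
          + (ax[2][None, None, :] - center_offset[2]) ** 2)
    return LabelMask((r2 <= radius_mm ** 2).astype(np.uint8), tuple(spacing),
                     (0.0, 0.0, 0.0))


def make_blob_mask(shape=(16, 16, 16), spacing=(1.5, 1.0, 2.0), seed=0,
                   threshold=0.55):
    """A random smooth blob; nonempty, not full."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), 3.0)
    noise = (noise - noise.min()) / np.ptp(noise)
    mask = (noise >= threshold).astype(np.uint8)
    assert 0 < mask.sum() < mask.size
    return LabelMask(mask, spacing, (0.0, 0.0, 0.0))


@pytest.fixture
def sphere_mask():
    return make_sphere_mask()


@pytest.fixture
def blob_mask():
    return make_blob_mask()


def ramp_volume(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), slope=2.0, axis=0):
    idx = np.arange(shape[axis], dtype=float) * spacing[axis]
    shp = [1, 1, 1]
    shp[axis] = shape[axis]
    data = np.broadcast_to(slope * idx.reshape(shp), shape).copy()
    return Volume(data, spacing, (0.0, 0.0, 0.0))
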