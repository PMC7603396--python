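import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from pulmodens.segmentation import LungMap
from pulmodens.volume_io import CTVolume


def make_ct(values, spacing_um=50.0):
    """CTVolume from any array-like (at least 3-D-able)."""
    arr = np.asarray(values, dtype=np.float32)
    if arr.ndim == 1:
        arr = arr[None, None, :]
    return CTVolume(voxels=arr, spacing_um=spacing_um)


def make_lung_map_for(ct, lung_mask=None):
    """All-lung map aligned to ``ct`` (or to the given boolean mask)."""
    labels = np.zeros(ct.shape, dtype=np.uint8)
    if lung_mask is None:
        labels[:] = 1
    else:
        labels[lung_mask] = 1
    return LungMap(labels=labels, spacing_um=ct.spacing_um)


def lung_ct(values, spacing_um=50.0):
    """(ct, map) pair where every voxel is lung with the given HU values."""
    ct = make_ct(values, spacing_um)
    return ct, make_lung_map_for(ct)


@pytest.fixture(scope="session")
def small_healthy_phantom():
    """One healthy phantom at a small grid, shared across tests."""
    from pulmodens.phantom import PhantomSpec, make_phantom

    spec = PhantomSpec(condition="healthy", dims=(96, 96, 96), seed=11)
    ct, truth = make_phantom(spec)
    return spec, ct, truth


@pytest.fixture(scope="session")
def small_severe_phantom():
    from pulmodens.phantom import PhantomSpec, make_phantom

    spec = PhantomSpec(condition="severe_blm", dims=(96, 96, 96), seed=12)
    ct, truth = make_phantom(spec)
    return spec, ct, truth
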