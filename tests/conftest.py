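import numpy as np
import pytest

from vessel4d import (
    AcquisitionProtocol,
    BinaryMask3D,
    Volume4D,
    default_phantom_spec,
    evaluate,
    generate_phantom,
)
from vessel4d.model import VesselSegmentationModel


def random_blob_mask(rng, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0), threshold=1.0):
    """A random nonempty mask: smoothed noise above a threshold."""
    from scipy import ndimage

    noise = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.0)
    mask = noise > threshold * noise.std()
    if not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    return BinaryMask3D(data=mask, spacing=spacing)


def random_volume4d(rng, shape=(3, 3, 3), t=5, spacing=(1.0, 1.0, 1.0)):
    exposures = rng.uniform(50, 250, size=t)
    data = rng.normal(50, 30, size=shape + (t,))
    return Volume4D(data=data, spacing=spacing, exposures=exposures)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def phantom_case():
    """One deterministic default phantom reused across read-only tests."""
    return generate_phantom(default_phantom_spec(variant=0), seed=42)


@pytest.fixture(scope="session")
def e2e_bundle():
    """Train on three phantom cases and segment a held-out fourth.

    The heavyweight shared fixture: 64^3 x 19 grids, default acquisition
    protocol, fixed seeds throughout.
    """
    train_cases = [
        generate_phantom(default_phantom_spec(variant=i), seed=101 + i) for i in range(3)
    ]
    held_out = generate_phantom(default_phantom_spec(variant=3), seed=104)
    results = VesselSegmentationModel(train_cases).fit(seed=7)
    segmentation = results.segment(held_out.volume, held_out.cavity)
    report = evaluate(segmentation, held_out.truth, exclude_boundary=False)
    return {
        "train_cases": train_cases,
        "held_out": held_out,
        "results": results,
        "segmentation": segmentation,
        "report": report,
    }
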