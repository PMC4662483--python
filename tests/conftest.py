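import numpy as np
import pytest

from woundquant import SyntheticSpec, generate_scratch_image


@pytest.fixture(scope="session")
def default_scratch():
    """A standard 100 px vertical wound at default noise, with ground truth."""
    spec = SyntheticSpec(wound_width=100.0, seed=42)
    img, gt = generate_scratch_image(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def noiseless_scratch():
    """Same geometry as default_scratch but without sensor noise."""
    spec = SyntheticSpec(wound_width=100.0, noise_sigma=0.0, seed=42)
    img, gt = generate_scratch_image(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def closed_monolayer():
    """An image that is 100% cell texture (wound width 0)."""
    img, gt = generate_scratch_image(SyntheticSpec(wound_width=0.0, seed=7))
    return img, gt


def iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 1.0
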