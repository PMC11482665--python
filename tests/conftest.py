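"""Shared fixtures: all test inputs are generated, none are stored."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.ndimage

from tinyscope.frames import Frame, FocusStack
from tinyscope.synthetic import _texture


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def textured_frame(rng) -> Frame:
    """A random smooth-textured 8-bit grayscale frame."""
    return Frame(_texture((128, 128), rng) * 200.0 + 20.0)


@pytest.fixture
def texture_array(rng) -> np.ndarray:
    return _texture((128, 128), rng) * 200.0 + 20.0


@pytest.fixture
def two_plane_stack(texture_array) -> FocusStack:
    """Layer A sharp on the left half, layer B sharp on the right half."""
    blurred = scipy.ndimage.gaussian_filter(texture_array, 4.0)
    layer_a = texture_array.copy()
    layer_a[:, 64:] = blurred[:, 64:]
    layer_b = texture_array.copy()
    layer_b[:, :64] = blurred[:, :64]
    return FocusStack([(0.0, Frame(layer_a)), (10.0, Frame(layer_b))])
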