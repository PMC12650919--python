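import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from sinusvol import Cavity, Channel, PhantomSpec


def disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2).astype(np.uint8)


def diamond(shape: tuple[int, int], center: tuple[int, int], radius: int) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (np.abs(yy - center[0]) + np.abs(xx - center[1]) <= radius).astype(np.uint8)


@pytest.fixture
def two_blob_channel():
    """Two 7-px-wide disc blobs joined by a 1-px channel of length 5.

    The channel mimics an invisible septum: with layer depth l=2 the
    erode/select/reconstruct procedure must keep the selected blob whole,
    drop the far blob, and leave at most a 2-px channel stub.
    Returns (mask, blob_a, blob_b, reference_pixel).
    """
    shape = (9, 21)
    blob_a = disc(shape, (4, 4), 3.5)
    blob_b = disc(shape, (4, 16), 3.5)
    mask = (blob_a | blob_b).astype(np.uint8)
    mask[4, 8:13] = 1  # channel, cols 8..12
    return mask, blob_a.astype(bool), blob_b.astype(bool), (4, 4)


@pytest.fixture
def sphere_spec():
    """Single noiseless spherical cavity, r=10 voxels, in a bright matrix."""
    return PhantomSpec(shape=(30, 44, 44),
                       cavities=(Cavity(center=(14.5, 21.5, 21.5), semi_axes=(10.0, 10.0, 10.0)),))


@pytest.fixture
def two_cavity_spec():
    """Two spherical cavities joined by a thin dark channel (septum scenario)."""
    return PhantomSpec(
        shape=(24, 30, 60),
        cavities=(Cavity(center=(11.5, 14.5, 14.5), semi_axes=(8.0, 8.0, 8.0)),
                  Cavity(center=(11.5, 14.5, 44.5), semi_axes=(8.0, 8.0, 8.0))),
        channels=(Channel(0, 1, width=1),),
    )


def random_mask(rng: np.random.Generator, max_side: int = 32, p: float | None = None) -> np.ndarray:
    """A random binary matrix; density drawn per mask unless given."""
    nrow = int(rng.integers(1, max_side + 1))
    ncol = int(rng.integers(1, max_side + 1))
    if p is None:
        p = float(rng.uniform(0.2, 0.8))
    return (rng.random((nrow, ncol)) < p).astype(np.uint8)
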