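"""Synthetic grayscale phantoms with known ground truth.

The phantoms emulate what the segmentation pipeline sees in a CBCT
study of the paranasal region: dark (radiolucent) air cavities embedded
in a bright (radiopaque) bony matrix, optionally joined by thin dark
channels that mimic the invisible-septum artefact, plus additive
Gaussian noise.  Cavities are ellipsoids so every phantom carries an
analytic volume and an exact foreground voxel count, giving the test
suite and the acceptance checks hard oracles.  A shrunken "post"
variant of the primary cavity emulates a pre/post surgical comparison
with a known true relative change (``1 − f³`` for isotropic shrink
factor ``f``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .image_io import GrayscaleStack, MaskStack

__all__ = [
    "Cavity",
    "Channel",
    "PhantomSpec",
    "PhantomResult",
    "generate_phantom",
    "generate_pre_post_pair",
]


@dataclass(frozen=True)
class Cavity:
    """An ellipsoidal air cavity: ``((z−cz)/az)² + ((y−cy)/ay)² + ((x−cx)/ax)² ≤ 1``."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    intensity_mean: int = 30


@dataclass(frozen=True)
class Channel:
    """An axis-aligned rectangular tube joining two cavity centers.

    The tube runs along the axis of greatest center separation with a
    ``width × width`` voxel cross-section, emulating a thin apparent
    connection through a septum that thresholding cannot see.
    """

    cavity_a: int
    cavity_b: int
    width: int = 1
    intensity_mean: int = 30


@dataclass(frozen=True)
class PhantomSpec:
    """Complete recipe for one phantom; identical spec + seed → identical output."""

    shape: tuple[int, int, int] = (40, 64, 64)
    cavities: tuple[Cavity, ...] = (Cavity(center=(19.5, 31.5, 31.5), semi_axes=(12.0, 12.0, 12.0)),)
    channels: tuple[Channel, ...] = ()
    matrix_intensity_mean: int = 200
    noise_sd: float = 0.0
    shrink_factor: float | tuple[float, float, float] = 0.9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        intensities = [self.matrix_intensity_mean]
        intensities += [c.intensity_mean for c in self.cavities]
        intensities += [c.intensity_mean for c in self.channels]
        if any(not 0 <= i <= 255 for i in intensities):
            raise ValueError("all intensity means must lie in [0, 255]")
        factors = self.shrink_factor if isinstance(self.shrink_factor, tuple) else (self.shrink_factor,)
        if any(not 0 < f <= 1 for f in factors):
            raise ValueError("shrink_factor components must lie in (0, 1]")
        for cav in self.cavities:
            if any(not 0 <= c < s for c, s in zip(cav.center, self.shape)):
                raise ValueError(f"cavity center {cav.center} outside shape {self.shape}")
        for ch in self.channels:
            for idx in (ch.cavity_a, ch.cavity_b):
                if not 0 <= idx < len(self.cavities):
                    raise ValueError(f"channel references unknown cavity {idx}")


@dataclass
class PhantomResult:
    """A generated phantom with its ground truth.

    ``truth`` marks the primary cavity (index 0) only; ``truth_all``
    additionally includes the other cavities and the channels.
    ``analytic_volume`` is the continuous ellipsoid volume of the primary
    cavity in voxel units; ``voxel_count`` its exact lattice count.
    """

    stack: GrayscaleStack
    truth: MaskStack
    truth_all: MaskStack
    analytic_volume: float
    voxel_count: int
    spec: PhantomSpec


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    az, ay, ax = semi_axes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _channel_mask(shape, spec: PhantomSpec, ch: Channel) -> np.ndarray:
    ca = np.array(spec.cavities[ch.cavity_a].center)
    cb = np.array(spec.cavities[ch.cavity_b].center)
    axis = int(np.argmax(np.abs(cb - ca)))
    lo = int(round(min(ca[axis], cb[axis])))
    hi = int(round(max(ca[axis], cb[axis])))
    mid = np.rint((ca + cb) / 2.0).astype(int)
    half_lo = (ch.width - 1) // 2
    half_hi = ch.width // 2
    mask = np.zeros(shape, dtype=bool)
    sl = [slice(None)] * 3
    for perp in range(3):
        if perp == axis:
            sl[perp] = slice(max(0, lo), hi + 1)
        else:
            sl[perp] = slice(max(0, mid[perp] - half_lo), mid[perp] + half_hi + 1)
    mask[tuple(sl)] = True
    return mask


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Render a phantom stack and its ground-truth masks from a spec."""
    shape = spec.shape
    image = np.full(shape, float(spec.matrix_intensity_mean))

    cavity_masks = [_ellipsoid_mask(shape, c.center, c.semi_axes) for c in spec.cavities]
    truth_all = np.zeros(shape, dtype=bool)
    for ch in spec.channels:
        m = _channel_mask(shape, spec, ch)
        image[m] = float(ch.intensity_mean)
        truth_all |= m
    for cav, m in zip(spec.cavities, cavity_masks):
        image[m] = float(cav.intensity_mean)
        truth_all |= m

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=shape)
    image = np.clip(np.floor(image + 0.5), 0, 255).astype(np.uint8)

    primary = spec.cavities[0]
    az, ay, ax = primary.semi_axes
    return PhantomResult(
        stack=GrayscaleStack(image, source_id=f"phantom(seed={spec.rng_seed})"),
        truth=MaskStack(cavity_masks[0]),
        truth_all=MaskStack(truth_all),
        analytic_volume=4.0 / 3.0 * np.pi * az * ay * ax,
        voxel_count=int(cavity_masks[0].sum()),
        spec=spec,
    )


def generate_pre_post_pair(spec: PhantomSpec) -> tuple[PhantomResult, PhantomResult]:
    """Generate a preoperative phantom and a shrunken postoperative variant.

    The post phantom scales the primary cavity's semi-axes by
    ``spec.shrink_factor`` (scalar → isotropic, giving a true continuous
    relative change of ``1 − f³``; per-axis factors multiply).  Noise in
    the post phantom uses an independent derived seed so the pair behaves
    like two separate acquisitions.
    """
    factors = spec.shrink_factor
    if not isinstance(factors, tuple):
        factors = (factors, factors, factors)
    pre = generate_phantom(spec)
    primary = spec.cavities[0]
    shrunk = replace(primary, semi_axes=tuple(a * f for a, f in zip(primary.semi_axes, factors)))
    post_spec = replace(spec,
                        cavities=(shrunk,) + spec.cavities[1:],
                        rng_seed=spec.rng_seed + 1)
    post = generate_phantom(post_spec)
    return pre, post
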