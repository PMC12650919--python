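"""Interval volumetry of a detected binary volume.

Detection errors are assumed to live on the boundary of the segmented
region, so the true volume is bracketed by two extreme masks computed
slice by slice:

* the *lower bound* keeps a pixel only when it and all four orthogonal
  neighbours are foreground (the plus-neighbourhood sum equals 5),
  removing the outermost layer;
* the *upper bound* keeps a pixel when it or any orthogonal neighbour is
  foreground (the sum is at least 1), adding one layer.

Each voxel contributes a cube of side ``L``; the reported volume is the
midpoint of the two bounds and the error half their width.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import ndimage

from .image_io import MaskStack

__all__ = [
    "VolumeEstimate",
    "RelativeChange",
    "lower_bound_mask",
    "upper_bound_mask",
    "estimate_volume",
    "relative_change",
    "percent_round",
]

_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass
class VolumeEstimate:
    """Volume bracketed as ``v_mid ± v_err`` under the cubic-voxel model."""

    n_lower: int
    n_detected: int
    n_upper: int
    voxel_side: float
    unit: str = "mm"

    def __post_init__(self) -> None:
        if self.voxel_side <= 0:
            raise ValueError("voxel_side must be positive")
        if not self.n_lower <= self.n_detected <= self.n_upper:
            raise ValueError("voxel counts must satisfy n_lower <= n_detected <= n_upper")

    @property
    def v_lower(self) -> float:
        return self.n_lower * self.voxel_side**3

    @property
    def v_upper(self) -> float:
        return self.n_upper * self.voxel_side**3

    @property
    def v_mid(self) -> float:
        return (self.v_lower + self.v_upper) / 2.0

    @property
    def v_err(self) -> float:
        return (self.v_upper - self.v_lower) / 2.0

    @property
    def v_detected(self) -> float:
        return self.n_detected * self.voxel_side**3

    def as_dict(self) -> dict:
        return {
            "n_lower": self.n_lower,
            "n_detected": self.n_detected,
            "n_upper": self.n_upper,
            "voxel_side": self.voxel_side,
            "unit": self.unit,
            "v_lower": self.v_lower,
            "v_detected": self.v_detected,
            "v_upper": self.v_upper,
            "v_mid": self.v_mid,
            "v_err": self.v_err,
        }

    def __str__(self) -> str:
        return f"{self.v_mid:.1f} ± {self.v_err:.1f} {self.unit}³"


@dataclass
class RelativeChange:
    """Relative pre/post volume change ``(v_pre − v_post) / v_pre``."""

    v_pre: float
    v_post: float

    def __post_init__(self) -> None:
        if self.v_pre <= 0:
            raise ValueError("v_pre must be positive")

    @property
    def delta_rel(self) -> float:
        return (self.v_pre - self.v_post) / self.v_pre

    @property
    def percent(self) -> float:
        """Percentage rounded half-up to one decimal."""
        return percent_round(self.delta_rel)


def percent_round(fraction: float, decimals: int = 1) -> float:
    """Render a fraction as a percentage, rounding half-up."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(fraction * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


def _check_binary_2d(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("mask must be binary (0/1)")
    return mask.astype(bool)


def lower_bound_mask(mask: np.ndarray) -> np.ndarray:
    """Remove the boundary layer: keep pixels whose plus-neighbourhood sums to 5.

    Out-of-bounds neighbours count as background, so pixels on the image
    edge never survive.
    """
    mask = _check_binary_2d(mask)
    return ndimage.binary_erosion(mask, structure=_CROSS, border_value=0).astype(np.uint8)


def upper_bound_mask(mask: np.ndarray) -> np.ndarray:
    """Add one layer: keep pixels whose plus-neighbourhood sum is at least 1."""
    mask = _check_binary_2d(mask)
    return ndimage.binary_dilation(mask, structure=_CROSS, border_value=0).astype(np.uint8)


def estimate_volume(mask: MaskStack, voxel_side: float, unit: str = "mm",
                    anisotropic: bool = False) -> VolumeEstimate:
    """Bracket the volume of a detected mask stack.

    The bound masks are computed per slice in 2D.  With
    ``anisotropic=True`` the per-voxel volume is ``dz*dy*dx`` from the
    mask's spacing instead of ``voxel_side**3``; the counts are
    unaffected.
    """
    if voxel_side <= 0:
        raise ValueError("voxel_side must be positive")
    n_lower = n_upper = 0
    for sl in mask.data:
        n_lower += int(lower_bound_mask(sl).sum())
        n_upper += int(upper_bound_mask(sl).sum())
    side = voxel_side
    if anisotropic:
        dz, dy, dx = mask.voxel_spacing
        side = float((dz * dy * dx) ** (1.0 / 3.0))
    return VolumeEstimate(n_lower, mask.n_voxels, n_upper, side, unit)


def relative_change(v_pre: float, v_post: float) -> RelativeChange:
    """Relative change of a paired pre/post volume measurement."""
    return RelativeChange(float(v_pre), float(v_post))
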