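"""Seeded detection of an air cavity across a binarized slice stack.

The detection works plane by plane.  Each slice is thresholded into a
binary matrix, whose foreground splits into *surfaces*: equivalence
classes of pixels connected through chains of neighbours at L1 distance
1, i.e. 4-connected components.  Starting from a user-supplied seed
voxel, the surface containing the seed is retained, and the detection
sweeps outward through adjacent planes: a surface in plane ``k +/- 1``
joins the detected volume when one of its pixels lies at in-plane L1
distance <= 1 (same position or a 4-neighbour offset) from an
already-retained pixel of plane ``k``.  Alternating forward and reverse
passes then incorporate surfaces that only become reachable late (e.g.
the second arm of a U-shaped cavity) until a fixpoint is reached.

Thin spurious connections between the target cavity and neighbouring
cavities ("invisible septa", a partial-volume artefact) are severed
per-slice by the erode/select/reconstruct procedure in
:mod:`sinusvol.septum`, invoked here when a layer depth ``l > 0`` is
configured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .image_io import GrayscaleStack, MaskStack
from .septum import remove_hidden_connections

__all__ = [
    "SeedPoint",
    "SegmentationParams",
    "SurfaceLabeling",
    "CROSS_2D",
    "binarize",
    "label_surfaces",
    "propagate_seed",
    "refine_detection",
    "segment_stack",
]

# plus-shaped structuring element: the L1 unit ball in the plane
CROSS_2D = ndimage.generate_binary_structure(2, 1)

Polarity = Literal["foreground_geq", "foreground_lt"]


@dataclass(frozen=True)
class SeedPoint:
    """A voxel asserted to lie inside the target cavity, 0-based (slice, row, col)."""

    slice: int
    row: int
    col: int

    def in_bounds(self, shape: tuple[int, int, int]) -> bool:
        return (0 <= self.slice < shape[0]
                and 0 <= self.row < shape[1]
                and 0 <= self.col < shape[2])


@dataclass
class SegmentationParams:
    """Tunable parameters of the detection.

    Parameters
    ----------
    k
        Global binarization threshold in [0, 255].
    polarity
        ``"foreground_geq"`` marks intensities >= k as foreground;
        ``"foreground_lt"`` marks intensities < k.  An air cavity is
        radiolucent (dark) inside radiopaque bone, so ``foreground_lt``
        is the physically natural choice for sinus detection.
    l
        Layer-removal depth for septum severing; 0 disables it.
    window_halfwidth
        Half-width of the in-plane window around reference pixels inside
        which septum-removal contiguity is evaluated.  ``None`` means
        ``2*l + 1``.
    """

    k: int
    polarity: Polarity = "foreground_lt"
    l: int = 0
    window_halfwidth: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.k <= 255:
            raise ValueError(f"threshold k must lie in [0, 255], got {self.k}")
        if self.polarity not in ("foreground_geq", "foreground_lt"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.l < 0:
            raise ValueError("layer depth l must be non-negative")
        if self.window_halfwidth is not None and self.window_halfwidth < 1:
            raise ValueError("window_halfwidth must be >= 1")


@dataclass
class SurfaceLabeling:
    """4-connected component labeling of one slice.

    ``labels`` assigns 0 to background and 1..n_surfaces to foreground;
    components are numbered by the row-major position of their first
    pixel, so the labeling is deterministic.
    """

    labels: np.ndarray
    n_surfaces: int


def binarize(image: np.ndarray, k: int, polarity: Polarity = "foreground_geq") -> np.ndarray:
    """Threshold a grayscale matrix into a 0/1 matrix with global threshold ``k``."""
    if not 0 <= k <= 255:
        raise ValueError(f"threshold k must lie in [0, 255], got {k}")
    image = np.asarray(image)
    if polarity == "foreground_geq":
        return (image >= k).astype(np.uint8)
    if polarity == "foreground_lt":
        return (image < k).astype(np.uint8)
    raise ValueError(f"unknown polarity {polarity!r}")


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("input must be binary (0/1)")
    return mask.astype(bool)


def label_surfaces(mask: np.ndarray) -> SurfaceLabeling:
    """Partition the foreground of one slice into 4-connected surfaces."""
    mask = _check_binary(mask)
    raw, n = ndimage.label(mask, structure=CROSS_2D)
    if n == 0:
        return SurfaceLabeling(raw.astype(np.int32), 0)
    # renumber by first (row-major) appearance so labels are deterministic
    flat = raw.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier indices overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, n + 1, dtype=np.int32)
    return SurfaceLabeling(remap[raw], n)


def _adjacent_reachable(labeling: SurfaceLabeling, reference: np.ndarray) -> np.ndarray:
    """Union of surfaces with a pixel at in-plane L1 distance <= 1 from ``reference``."""
    if not reference.any():
        return np.zeros_like(reference, dtype=bool)
    contact = ndimage.binary_dilation(reference, structure=CROSS_2D)
    hit = np.unique(labeling.labels[contact & (labeling.labels > 0)])
    if hit.size == 0:
        return np.zeros_like(reference, dtype=bool)
    return np.isin(labeling.labels, hit)


def _select_slice(slice_fg: np.ndarray, reference: np.ndarray,
                  params: SegmentationParams | None) -> np.ndarray:
    """Retained set of one slice given reference pixels (seed or adjacent plane)."""
    labeling = label_surfaces(slice_fg)
    plain = _adjacent_reachable(labeling, reference)
    if params is None or params.l == 0 or not plain.any():
        return plain
    refs = np.argwhere(reference & ndimage.binary_dilation(plain, structure=CROSS_2D))
    if refs.size == 0:
        return plain
    with warnings.catch_warnings():
        # erosion emptying a tiny surface (cavity cap, boundary crumb) is
        # routine inside the sweep; the fallback keeps the surface whole
        warnings.simplefilter("ignore")
        return remove_hidden_connections(
            plain.astype(np.uint8),
            {(int(r), int(c)) for r, c in refs},
            params.l,
            window_halfwidth=params.window_halfwidth,
        ).astype(bool)


def propagate_seed(binary_stack: MaskStack, seed: SeedPoint,
                   params: SegmentationParams | None = None) -> MaskStack:
    """Single outward sweep from the seed slice through adjacent planes.

    In the seed's slice exactly the seed's surface is retained; each
    neighbouring plane then contributes the surfaces contiguous (in-plane
    L1 distance <= 1) with the retained pixels of the plane just
    processed, sweeping outward in both directions.  When ``params.l > 0``
    each slice's retained set additionally passes through septum removal
    against the reference pixels that linked it.
    """
    fg = binary_stack.data
    if not seed.in_bounds(fg.shape):
        raise IndexError(f"seed {seed} outside stack of shape {fg.shape}")
    if not fg[seed.slice, seed.row, seed.col]:
        raise ValueError(f"seed {seed} is background after binarization")

    retained = np.zeros_like(fg, dtype=bool)
    seed_ref = np.zeros(fg.shape[1:], dtype=bool)
    seed_ref[seed.row, seed.col] = True
    labeling = label_surfaces(fg[seed.slice])
    seed_surface = labeling.labels == labeling.labels[seed.row, seed.col]
    retained[seed.slice] = seed_surface
    if params is not None and params.l > 0:
        cleaned = _select_slice(fg[seed.slice], seed_ref, params)
        if cleaned.any():
            retained[seed.slice] = cleaned
        else:
            warnings.warn(
                "septum removal emptied the seed slice (seed not inside the "
                "eroded core); keeping the seed surface unprocessed",
                stacklevel=2)

    for direction in (1, -1):
        s = seed.slice + direction
        while 0 <= s < fg.shape[0]:
            retained[s] = _select_slice(fg[s], retained[s - direction], params)
            if not retained[s].any():
                break
            s += direction
    return MaskStack(retained, binary_stack.voxel_spacing)


def refine_detection(binary_stack: MaskStack, initial: MaskStack,
                     seed: SeedPoint, params: SegmentationParams | None = None) -> MaskStack:
    """Iterate forward and reverse sweeps until no pixel is added.

    Each pass visits the slices in order (alternating direction between
    passes) and adds every surface contiguous with retained pixels in
    either adjacent plane.  The result is a fixpoint: a superset of
    ``initial``, a subset of the binary foreground, and idempotent under
    further refinement.
    """
    fg = binary_stack.data.astype(bool)
    retained = initial.data.astype(bool).copy()
    if not (retained <= fg).all():
        raise ValueError("initial detection must be a subset of the binary foreground")

    n_slices = fg.shape[0]
    max_passes = max(2 * n_slices, 4)
    for p in range(max_passes):
        order = range(n_slices) if p % 2 == 0 else range(n_slices - 1, -1, -1)
        added = False
        for s in order:
            reference = np.zeros(fg.shape[1:], dtype=bool)
            if s > 0:
                reference |= retained[s - 1]
            if s < n_slices - 1:
                reference |= retained[s + 1]
            new = _select_slice(fg[s] & ~retained[s], reference, params)
            if new.any():
                retained[s] |= new
                added = True
        if not added:
            break
    else:
        raise RuntimeError(f"detection did not stabilise within {max_passes} passes")
    return MaskStack(retained, binary_stack.voxel_spacing)


def segment_stack(stack: GrayscaleStack, seed: SeedPoint,
                  params: SegmentationParams) -> MaskStack:
    """Full detection pipeline: binarize, propagate from the seed, refine.

    Raises ``ValueError`` naming the seed intensity and threshold when the
    seed lands on background, which usually means the polarity or ``k``
    is wrong for the scan at hand.
    """
    fg = np.stack([binarize(sl, params.k, params.polarity) for sl in stack.data])
    binary = MaskStack(fg, stack.voxel_spacing)
    if not seed.in_bounds(fg.shape):
        raise IndexError(f"seed {seed} outside stack of shape {fg.shape}")
    if not fg[seed.slice, seed.row, seed.col]:
        intensity = int(stack.data[seed.slice, seed.row, seed.col])
        raise ValueError(
            f"seed {seed} has intensity {intensity}, which is background for "
            f"k={params.k} with polarity {params.polarity!r}")
    initial = propagate_seed(binary, seed, params)
    return refine_detection(binary, initial, seed, params)
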