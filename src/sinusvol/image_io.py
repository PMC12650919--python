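"""Reading and writing grayscale slice stacks and binary mask stacks.

The segmentation pipeline operates on ordered stacks of 2D integer
matrices with intensities in [0, 255] (the canonical representation of a
CBCT study exported slice by slice).  Two on-disk layouts are supported:

* a DICOM series, one file per slice, read with :mod:`pydicom`;
* a directory of 8-bit grayscale image files (PNG/TIFF), one per slice,
  ordered by natural sort of their filenames.

Binary masks round-trip through per-slice PNG files (0/255) or a single
NIfTI volume.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "GrayscaleStack",
    "MaskStack",
    "read_stack",
    "read_mask",
    "write_mask",
    "write_stack",
    "rescale_to_8bit",
]


@dataclass
class GrayscaleStack:
    """An ordered stack of 2D intensity matrices.

    Parameters
    ----------
    data
        Integer array of shape ``(n_slices, n_rows, n_cols)`` with every
        value in ``[0, 255]``.  Slices are ordered along the scan axis
        (ascending physical position).
    voxel_spacing
        ``(dz, dy, dx)`` in millimetres; all strictly positive.
    source_id
        Free-text provenance (directory name, series UID, phantom spec).
    """

    data: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (slices, rows, cols), got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("stack intensities must be integers")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 255):
            raise ValueError("stack intensities must lie in [0, 255]")
        self.data = self.data.astype(np.uint8, copy=False)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be three strictly positive lengths")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclass
class MaskStack:
    """A binary volume aligned voxel-for-voxel with a :class:`GrayscaleStack`."""

    data: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be 0/1")
            arr = arr.astype(bool)
        self.data = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MaskStack):
            return NotImplemented
        return self.shape == other.shape and bool(np.array_equal(self.data, other.data))


_NUM_RE = re.compile(r"(\d+)")


def _natural_key(name: str) -> tuple:
    return tuple(int(tok) if tok.isdigit() else tok for tok in _NUM_RE.split(name))


def _sorted_files(path: Path, suffixes: Sequence[str]) -> list[Path]:
    files = [p for p in path.iterdir() if p.is_file() and p.suffix.lower() in suffixes]
    if not files:
        raise FileNotFoundError(f"no slice files with suffix {suffixes} in {path}")
    return sorted(files, key=lambda p: _natural_key(p.name))


def rescale_to_8bit(raw: np.ndarray, window_center: float, window_width: float) -> np.ndarray:
    """Linearly window a signed-integer matrix onto the 0-255 range.

    The interval ``[center - width/2, center + width/2]`` maps linearly to
    ``[0, 255]``; values outside it clamp to the endpoints.  Rounding is
    half-up, so a raw value exactly at the window center maps to 128.
    """
    if window_width <= 0:
        raise ValueError("window_width must be positive")
    raw = np.asarray(raw, dtype=np.float64)
    lo = window_center - window_width / 2.0
    scaled = (raw - lo) / window_width * 255.0
    # np.round is banker's rounding; the contract is round-half-up
    out = np.floor(np.clip(scaled, 0.0, 255.0) + 0.5)
    return np.clip(out, 0, 255).astype(np.uint8)


def _read_dicom_series(path: Path, voxel_spacing=None,
                       window: tuple[float, float] | None = None) -> GrayscaleStack:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", ".dicom", ""))
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise FileNotFoundError(f"no readable DICOM files in {path}")
    series = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(series) > 1:
        raise ValueError(f"directory {path} mixes {len(series)} DICOM series")

    def position(ds) -> float:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=position)
    positions = [position(ds) for ds in datasets]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate slice positions in DICOM series")

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        slices.append(arr)
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"mixed slice dimensions in series: {shapes}")
    vol = np.stack(slices)
    if window is None:
        lo, hi = float(vol.min()), float(vol.max())
        if hi == lo:
            hi = lo + 1.0
        window = ((lo + hi) / 2.0, hi - lo)
    vol8 = rescale_to_8bit(vol, *window)

    if voxel_spacing is None:
        ds0 = datasets[0]
        px = getattr(ds0, "PixelSpacing", [1.0, 1.0])
        if len(positions) > 1:
            dz = abs(positions[1] - positions[0])
        else:
            dz = float(getattr(ds0, "SliceThickness", 1.0))
        voxel_spacing = (dz, float(px[0]), float(px[1]))
    return GrayscaleStack(vol8, voxel_spacing, source_id=str(path))


def _read_image_directory(path: Path, voxel_spacing=None) -> GrayscaleStack:
    import imageio.v3 as iio

    files = _sorted_files(path, (".png", ".tif", ".tiff", ".bmp"))
    slices = []
    for f in files:
        arr = np.asarray(iio.imread(f))
        if arr.ndim == 3:
            if arr.shape[2] in (3, 4) and np.all(arr[..., 0] == arr[..., 1]) and np.all(arr[..., 0] == arr[..., 2]):
                arr = arr[..., 0]  # gray stored as RGB(A)
            else:
                raise ValueError(f"{f} is not a grayscale image")
        slices.append(arr)
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"mixed slice dimensions: {shapes}")
    vol = np.stack(slices)
    if vol.min() < 0 or vol.max() > 255:
        raise ValueError("image-directory stacks must be 8-bit (0-255)")
    return GrayscaleStack(vol.astype(np.uint8),
                          voxel_spacing or (1.0, 1.0, 1.0),
                          source_id=str(path))


def read_stack(path, format: str = "image_directory", *, voxel_spacing=None,
               window: tuple[float, float] | None = None) -> GrayscaleStack:
    """Read a grayscale slice stack from disk.

    Parameters
    ----------
    path
        Directory containing one file per slice.
    format
        ``"dicom_series"`` or ``"image_directory"``.
    voxel_spacing
        ``(dz, dy, dx)`` in mm.  Required metadata for image directories
        (defaults to unit spacing); overrides DICOM metadata when given.
    window
        Optional ``(center, width)`` for DICOM intensity windowing; the
        default windows the full data range onto [0, 255].  Intensities
        already in [0, 255] with the default window pass through unchanged
        only up to the series' own dynamic range.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dicom_series":
        return _read_dicom_series(path, voxel_spacing, window)
    if format == "image_directory":
        return _read_image_directory(path, voxel_spacing)
    raise ValueError(f"unknown stack format: {format!r}")


def write_stack(stack: GrayscaleStack, path) -> None:
    """Write a grayscale stack as a directory of PNG slices."""
    import imageio.v3 as iio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(stack.n_slices)))
    for i in range(stack.n_slices):
        iio.imwrite(path / f"slice_{i:0{width}d}.png", stack.data[i])


def write_mask(mask: MaskStack, path, format: str = "image_directory") -> None:
    """Persist a binary mask stack (losslessly round-trips via :func:`read_mask`)."""
    path = Path(path)
    if format == "image_directory":
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(mask.shape[0])))
        for i in range(mask.shape[0]):
            iio.imwrite(path / f"mask_{i:0{width}d}.png",
                        (mask.data[i].astype(np.uint8) * 255))
    elif format == "nifti":
        import nibabel as nib

        dz, dy, dx = mask.voxel_spacing
        affine = np.diag([dx, dy, dz, 1.0])
        # store as (cols, rows, slices) so the affine carries the spacing
        img = nib.Nifti1Image(mask.data.astype(np.uint8).transpose(2, 1, 0), affine)
        nib.save(img, str(path))
    else:
        raise ValueError(f"unknown mask format: {format!r}")


def read_mask(path, format: str = "image_directory",
              voxel_spacing=(1.0, 1.0, 1.0)) -> MaskStack:
    """Read a binary mask stack written by :func:`write_mask`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "image_directory":
        import imageio.v3 as iio

        files = _sorted_files(path, (".png", ".tif", ".tiff"))
        slices = [np.asarray(iio.imread(f)) > 127 for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"mixed slice dimensions: {shapes}")
        return MaskStack(np.stack(slices), voxel_spacing)
    if format == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj).transpose(2, 1, 0) > 0
        zooms = img.header.get_zooms()[:3]
        return MaskStack(data, (float(zooms[2]), float(zooms[1]), float(zooms[0])))
    raise ValueError(f"unknown mask format: {format!r}")
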