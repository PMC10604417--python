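"""Slice-stack and 3D volume I/O for CT spike scans.

A reconstructed micro-CT scan arrives as a directory of ordered 8-bit
grayscale transaxial slice images (BMP or PNG) with a known isotropic pixel
size P in micrometres.  This module reads such stacks into a single
``VoxelVolume``, masks out the bright circular specimen-holder ring that
surrounds every slice, resizes slices for the segmentation network, and
stacks processed binary masks into a NIfTI volume whose header records the
voxel spacing in millimetres.

Axis convention (used everywhere in this package): arrays are indexed
``(z, y, x)`` with ``z`` the slice index increasing from the first file in
lexicographic filename order.  NIfTI files are written in the conventional
``(x, y, z)`` order and transposed back on load, so the round trip is the
identity on both voxels and pixel size.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

log = logging.getLogger("spikect")

_IMAGE_SUFFIXES = {".png", ".bmp"}


@dataclass
class VoxelVolume:
    """A 3D grid of 8-bit intensities with isotropic pixel size.

    Attributes
    ----------
    voxels : ndarray, shape (nz, ny, nx), uint8
        Grayscale intensities, ``z`` = slice index.
    pixel_size_um : float
        Isotropic voxel side length P in micrometres (typically 75-95 for
        the scans this package targets).
    source_id : str
        Free-text provenance tag (scan/accession name).
    """

    voxels: np.ndarray
    pixel_size_um: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a non-empty 3D (z, y, x) array")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]


@dataclass
class BinaryVolume:
    """A 3D {0,1} mask volume; 1 marks grain tissue."""

    voxels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3D (z, y, x)")
        vals = np.unique(self.voxels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("BinaryVolume values must be in {0, 1}")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]


@dataclass(frozen=True)
class CircularROI:
    """Circular region of interest used to mask out the holder ring.

    ``center_xy`` is (x, y) in pixel coordinates (x = column, y = row).
    Pixels at distance >= ``radius`` from the center are discarded.
    """

    center_xy: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError("roi radius must be positive")


# ---------------------------------------------------------------------------
# Slice-stack reading / writing
# ---------------------------------------------------------------------------

def _numeric_key(name: str) -> tuple:
    """Sort key treating digit runs as integers (natural order)."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def read_slice_stack(dir_path: str | Path, pixel_size_um: float) -> VoxelVolume:
    """Read an ordered directory of 8-bit grayscale slice images.

    Slices are ordered by lexicographic filename; the z index of a slice is
    its position in that order.  Filenames whose lexicographic order differs
    from their natural numeric order (``slice_10`` before ``slice_2``) are
    rejected with advice to zero-pad, since silently mis-ordered stacks
    produce scrambled spikes.

    Non-8-bit images are converted to 8-bit with a logged warning.
    """
    dir_path = Path(dir_path)
    files = sorted(
        p for p in dir_path.iterdir()
        if p.is_file() and p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if not files:
        raise FileNotFoundError(f"no slice images (.png/.bmp) found in {dir_path}")

    names = [p.name for p in files]
    if names != sorted(names, key=_numeric_key):
        raise ValueError(
            "slice filenames are lexicographically out of numeric order "
            "(e.g. slice_10 sorts before slice_2); zero-pad slice indices "
            "so lexicographic order equals acquisition order"
        )

    slices = []
    for p in files:
        with Image.open(p) as img:
            if img.mode != "L":
                log.warning("converting non-8-bit image %s (mode %s) to 8-bit", p.name, img.mode)
                img = img.convert("L")
            slices.append(np.asarray(img, dtype=np.uint8))
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"slice images have mixed dimensions: {sorted(shapes)}")
    return VoxelVolume(np.stack(slices, axis=0), pixel_size_um, source_id=dir_path.name)


def write_slice_stack(volume: VoxelVolume | np.ndarray, dir_path: str | Path,
                      fmt: str = "png", prefix: str = "slice_") -> list[Path]:
    """Write one 8-bit image per z index with zero-padded sortable names.

    Lossless (PNG or uncompressed BMP): re-reading with
    :func:`read_slice_stack` reproduces the voxel array bit-exactly.
    """
    voxels = volume.voxels if isinstance(volume, VoxelVolume) else np.asarray(volume)
    if voxels.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) volume")
    if fmt.lower() not in ("png", "bmp"):
        raise ValueError("fmt must be 'png' or 'bmp'")
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(voxels.shape[0] - 1)))
    paths = []
    for z in range(voxels.shape[0]):
        p = dir_path / f"{prefix}{z:0{width}d}.{fmt.lower()}"
        Image.fromarray(voxels[z].astype(np.uint8), mode="L").save(p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Holder removal
# ---------------------------------------------------------------------------

def remove_holder(slice_image: np.ndarray, roi: CircularROI) -> np.ndarray:
    """Zero all pixels at distance >= roi.radius from roi.center.

    The scanned spike sits inside a plastic holder whose wall appears as a
    bright ring on every transaxial slice; keeping only the circular
    interior removes it.  Idempotent; the circle is implicitly clipped to
    the image bounds.
    """
    img = np.asarray(slice_image)
    if img.ndim != 2:
        raise ValueError("slice must be 2D")
    cx, cy = roi.center_xy
    yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
    outside = (xx - cx) ** 2 + (yy - cy) ** 2 >= roi.radius ** 2
    out = img.copy()
    out[outside] = 0
    return out


def detect_holder_roi(slice_image: np.ndarray, margin: float = 2.0) -> CircularROI:
    """Estimate the holder ROI from the radial intensity profile.

    Assumes the holder ring is concentric with the image center (how the
    scanner reconstructs it).  Finds the brightest annulus in the outer half
    of the radial mean-intensity profile and returns a circle just inside
    it.  Intended as a convenience; an explicit per-scan ROI from config is
    preferred.
    """
    img = np.asarray(slice_image, dtype=float)
    h, w = img.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.ogrid[:h, :w]
    r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    rbin = r.astype(int)
    prof = np.bincount(rbin.ravel(), weights=img.ravel()) / np.maximum(
        np.bincount(rbin.ravel()), 1
    )
    lo = len(prof) // 2
    ring_r = lo + int(np.argmax(prof[lo:]))
    return CircularROI(center_xy=(cx, cy), radius=max(1.0, ring_r - margin))


# ---------------------------------------------------------------------------
# Resizing
# ---------------------------------------------------------------------------

def resize_slice(image: np.ndarray, target: tuple[int, int], mode: str) -> np.ndarray:
    """Resize a 2D slice.

    ``mode='intensity'`` uses bilinear interpolation (for grayscale input to
    the network); ``mode='mask'`` uses nearest-neighbour, which preserves
    the {0,1} value set so predicted masks can be restored to the original
    slice dimensions.
    """
    if mode not in ("intensity", "mask"):
        raise ValueError("mode must be 'intensity' or 'mask'")
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    th, tw = target
    if th < 1 or tw < 1:
        raise ValueError("target dims must be >= 1")
    if img.shape == (th, tw):
        return img.copy()
    if mode == "mask":
        out = _sk_resize(img, (th, tw), order=0, preserve_range=True,
                         anti_aliasing=False)
        return out.astype(img.dtype)
    out = _sk_resize(img.astype(np.float64), (th, tw), order=1,
                     preserve_range=True, anti_aliasing=False)
    if np.issubdtype(img.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255)
    return out.astype(img.dtype)


# ---------------------------------------------------------------------------
# NIfTI stacking
# ---------------------------------------------------------------------------

def stack_and_save(masks: Sequence[np.ndarray], pixel_size_um: float,
                   path: str | Path) -> Path:
    """Stack ordered 2D binary masks and save as one NIfTI volume.

    The header voxel spacing is P/1000 mm on each axis.  Data are stored in
    (x, y, z) order as NIfTI convention expects; :func:`load_volume`
    transposes back to (z, y, x), making the round trip exact.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("empty mask list")
    arrs = [np.asarray(m) for m in masks]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"masks have mixed dimensions: {sorted(shapes)}")
    vol = np.stack(arrs, axis=0).astype(np.uint8)  # (z, y, x)
    return save_volume(vol, pixel_size_um, path)


def save_volume(voxels: np.ndarray, pixel_size_um: float, path: str | Path) -> Path:
    """Save a (z, y, x) integer volume as NIfTI with P recorded in mm."""
    path = Path(path)
    mm = pixel_size_um / 1000.0
    data = np.ascontiguousarray(np.asarray(voxels).transpose(2, 1, 0))
    img = nib.Nifti1Image(data, affine=np.diag([mm, mm, mm, 1.0]))
    img.header.set_zooms((mm, mm, mm))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path, binary: bool = False):
    """Load a NIfTI volume saved by this package back to (z, y, x).

    Returns a :class:`BinaryVolume` when ``binary`` is true (values are
    binarized at > 0), else a :class:`VoxelVolume`.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    voxels = np.ascontiguousarray(data.transpose(2, 1, 0))
    pixel_size_um = float(img.header.get_zooms()[0]) * 1000.0
    if binary:
        return BinaryVolume((voxels > 0).astype(np.uint8), pixel_size_um)
    return VoxelVolume(voxels.astype(np.uint8), pixel_size_um,
                       source_id=Path(path).name)
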