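"""Image and metadata I/O.

Reads mid-sagittal MRI slices (DICOM or 8-bit greyscale PNG) and their
pixel-spacing metadata, and normalizes every image to the pipeline's
working convention: a square 384x384 grid with a single scalar pixel
spacing in mm/pixel.

Coordinates follow the standard image convention throughout the package:
row/column with the origin at the top-left, y (row) increasing downward,
so "the lowest point" of a structure is the one with the maximal row
index.  Points are (x, y) = (column, row) pairs when treated as 2-D
vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import MetadataError, UnsupportedGeometryError

#: Working image dimension every study is resampled to.
WORKING_DIM = 384


def rescale_pixel_spacing(ps: float, dm: int) -> float:
    """Pixel spacing after resampling a ``dm``-pixel square image to 384.

    The physical field of view is unchanged by resampling, so the new
    spacing is ``ps * dm / 384`` (mm/pixel).

    Parameters
    ----------
    ps : original pixel spacing, mm/pixel (> 0).
    dm : original square image dimension, pixels (> 0).
    """
    if ps <= 0 or dm <= 0:
        raise ValueError(f"pixel spacing and dimension must be positive, got ps={ps}, dm={dm}")
    return ps * dm / WORKING_DIM


@dataclass(frozen=True)
class ImageMeta:
    """Scalar geometry metadata of a square mid-sagittal slice."""

    pixel_spacing_mm: float
    dimension_px: int

    def __post_init__(self):
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.dimension_px <= 0:
            raise ValueError("image dimension must be positive")

    @property
    def rescaled_spacing_mm(self) -> float:
        """Pixel spacing in the 384x384 working frame."""
        return rescale_pixel_spacing(self.pixel_spacing_mm, self.dimension_px)

    def to_json(self) -> str:
        return json.dumps(
            {
                "pixel_spacing": self.pixel_spacing_mm,
                "dimension": self.dimension_px,
                "rescaled_spacing": self.rescaled_spacing_mm,
            }
        )


@dataclass
class GreyImage:
    """A square greyscale image with intensities in [0, 255] plus metadata."""

    pixels: np.ndarray
    meta: ImageMeta

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise UnsupportedGeometryError(f"expected a square 2-D image, got shape {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")

    @property
    def shape(self):
        return self.pixels.shape


def read_dicom_meta(path) -> ImageMeta:
    """Extract Pixel Spacing and Image Dimension from a DICOM file.

    Requires identical x/y spacing and square row/column counts; clinical
    sagittal series in scope satisfy both, anything else is rejected.
    """
    import pydicom

    ds = pydicom.dcmread(str(path), stop_before_pixels=True)
    try:
        spacing = [float(v) for v in ds.PixelSpacing]
        rows, cols = int(ds.Rows), int(ds.Columns)
    except AttributeError as exc:
        raise MetadataError(f"missing DICOM attribute in {path}: {exc}") from exc
    if len(spacing) != 2 or abs(spacing[0] - spacing[1]) > 1e-6:
        raise UnsupportedGeometryError(f"anisotropic pixel spacing {spacing} in {path}")
    if rows != cols:
        raise UnsupportedGeometryError(f"non-square image {rows}x{cols} in {path}")
    return ImageMeta(pixel_spacing_mm=spacing[0], dimension_px=rows)


def read_dicom_grey(path) -> GreyImage:
    """Read a DICOM slice and convert its stored values to 8-bit greyscale.

    Stored values are mapped to [0, 255] by per-image linear min-max
    scaling (the simplest reproducible windowing; constant images map
    to 0).
    """
    import pydicom

    meta = read_dicom_meta(path)
    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(float)
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo) * 255.0
    else:
        arr = np.zeros_like(arr)
    return GreyImage(pixels=arr, meta=meta)


def read_grey_png(path, pixel_spacing_mm: float) -> GreyImage:
    """Read an 8-bit greyscale PNG with caller-supplied pixel spacing."""
    arr = np.asarray(Image.open(path).convert("L"), dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise UnsupportedGeometryError(f"non-square PNG {arr.shape} in {path}")
    return GreyImage(pixels=arr, meta=ImageMeta(pixel_spacing_mm, arr.shape[0]))


def write_grey_png(image: GreyImage, path) -> None:
    """Write an 8-bit greyscale PNG plus a JSON metadata sidecar."""
    path = Path(path)
    Image.fromarray(np.clip(np.round(image.pixels), 0, 255).astype(np.uint8), mode="L").save(path)
    path.with_suffix(".json").write_text(image.meta.to_json())


def resample_to_working(pixels: np.ndarray, is_label: bool = False) -> np.ndarray:
    """Resample a square pixel grid to 384x384.

    Cubic interpolation for intensity images, nearest-neighbour for
    label images (which must never gain label values).
    """
    from skimage.transform import resize

    pixels = np.asarray(pixels)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise UnsupportedGeometryError(f"expected a square image, got {pixels.shape}")
    if pixels.shape[0] == WORKING_DIM:
        return pixels.copy()
    if is_label:
        out = resize(
            pixels, (WORKING_DIM, WORKING_DIM), order=0, preserve_range=True, anti_aliasing=False
        )
        return out.astype(pixels.dtype)
    out = resize(
        pixels.astype(float), (WORKING_DIM, WORKING_DIM), order=3, preserve_range=True, anti_aliasing=False
    )
    return np.clip(out, 0, 255)


def resample_to_384(image: GreyImage) -> GreyImage:
    """Resample a GreyImage to the 384x384 working frame (cubic)."""
    out = resample_to_working(image.pixels, is_label=False)
    return GreyImage(pixels=out, meta=replace(image.meta))
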