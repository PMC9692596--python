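"""Grayscale image container, histogramming, physical scale, and file I/O.

The container models an 8-bit TEM micrograph ``f(i, j)`` together with the
physical edge length of one pixel. Native tomographic acquisitions in this
workflow are ~0.97 nm/pixel; block downsampling by a linear factor k turns
that into 0.97·k nm/pixel while averaging intensities, mirroring the size
reduction applied to large micrographs before segmentation.

Coordinate convention everywhere: row-major, 0-based, origin top-left,
half-open ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Union

import numpy as np
import tifffile
from PIL import Image

from ._rounding import round_half_up_array
from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .roi import RegionOfInterest

#: Native acquisition scale, nm per pixel (9.7 Å).
DEFAULT_PIXEL_SIZE_NM = 0.97

# ITU-R BT.601 luma weights for RGB -> grayscale conversion.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2-D 8-bit intensity raster with a physical pixel size.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array of intensities in [0, 255].
    pixel_size_nm
        Physical edge length of one pixel in nanometres; must be positive.
    """

    pixels: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError(
                f"image must be a non-empty 2-D raster, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer):
                raise ValidationError("pixel intensities must be integers")
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("pixel intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if not self.pixel_size_nm > 0:
            raise ValidationError(
                f"pixel_size_nm must be positive, got {self.pixel_size_nm}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class IntensityHistogram:
    """Gray-level histogram with exactly 256 bins (levels 0-255)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (256,):
            raise ValidationError("histogram must have exactly 256 bins")
        if (c < 0).any():
            raise ValidationError("histogram counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def occupied_levels(self) -> np.ndarray:
        """Gray levels with non-zero count, ascending."""
        return np.flatnonzero(self.counts)


def read_image(path: Union[str, Path], pixel_size_nm: float) -> GrayImage:
    """Read a TIFF or PNG micrograph as an 8-bit grayscale image.

    RGB(A) inputs are converted with BT.601 luminance weights and rounded
    half-up; 16-bit inputs are rescaled by 255/65535. The physical pixel
    size is never read from file metadata — it is always supplied by the
    caller.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read image: no such file {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except Exception as exc:  # pragma: no cover - decoder-specific
        raise IOError(f"cannot decode image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValidationError(f"zero-size raster in {path}")
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValidationError(
                f"unsupported channel count {arr.shape[2]} in {path}"
            )
        arr = round_half_up_array(arr.astype(float) @ _LUMA_WEIGHTS)
    elif arr.ndim != 2:
        raise ValidationError(f"unsupported raster rank {arr.ndim} in {path}")
    if arr.dtype == np.uint16:
        arr = round_half_up_array(arr.astype(float) * (255.0 / 65535.0))
    arr = np.clip(arr, 0, 255).astype(np.uint8)
    return GrayImage(pixels=arr, pixel_size_nm=pixel_size_nm)


def write_image(img: GrayImage, path: Union[str, Path]) -> None:
    """Write an 8-bit TIFF or PNG (chosen by file suffix)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels)
    else:
        Image.fromarray(img.pixels, mode="L").save(path)


def block_downsample(img: GrayImage, factor: int) -> GrayImage:
    """Reduce resolution by averaging factor x factor pixel blocks.

    Each output pixel is the round-half-up mean of one complete block;
    trailing rows/columns that do not fill a block are dropped. The pixel
    size scales by ``factor`` per axis (0.97 nm -> 3.88 nm at factor 4).
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValidationError(f"downsample factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    if factor == 1:
        return GrayImage(pixels=img.pixels.copy(), pixel_size_nm=img.pixel_size_nm)
    h = (img.height // factor) * factor
    w = (img.width // factor) * factor
    if h == 0 or w == 0:
        raise ValidationError(
            f"image {img.shape} too small for downsample factor {factor}"
        )
    blocks = img.pixels[:h, :w].astype(float)
    blocks = blocks.reshape(h // factor, factor, w // factor, factor)
    means = blocks.mean(axis=(1, 3))
    out = np.clip(round_half_up_array(means), 0, 255).astype(np.uint8)
    return GrayImage(pixels=out, pixel_size_nm=img.pixel_size_nm * factor)


def histogram(
    img: GrayImage,
    mask: Optional[Union["RegionOfInterest", np.ndarray]] = None,
) -> IntensityHistogram:
    """256-bin gray-level histogram of the image or of a masked region."""
    if mask is None:
        values = img.pixels.ravel()
    else:
        m = getattr(mask, "mask", mask)
        m = np.asarray(m, dtype=bool)
        if m.shape != img.shape:
            raise ValidationError(
                f"mask shape {m.shape} does not match image shape {img.shape}"
            )
        if not m.any():
            raise ValidationError("ROI selects zero pixels")
        values = img.pixels[m]
    counts = np.bincount(values, minlength=256)
    return IntensityHistogram(counts=counts)
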