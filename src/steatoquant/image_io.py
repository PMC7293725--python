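"""Reading and writing slide photomicrographs and binary masks.

Slides are plain 8-bit RGB rasters (TIFF/PNG/JPEG); masks are written as
single-channel PNGs with 0/255 coding so that every artifact stays
losslessly round-trippable. Pixel indexing is 0-based, row-major, origin
at the top-left corner.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image, UnidentifiedImageError

from .errors import FormatError

_SUPPORTED_SUFFIXES = {".tif", ".tiff", ".png", ".jpg", ".jpeg"}


@dataclasses.dataclass
class SlideImage:
    """An RGB photomicrograph, the unit of quantification.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (height, width, 3)
        8-bit RGB pixel grid.
    pixel_size_um : float, optional
        Physical pixel pitch in micrometres, when the acquisition is
        calibrated. Area fractions do not require it.
    source_id : str
        Free-text identifier, by default the file stem.
    """

    pixels: np.ndarray
    pixel_size_um: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB pixels, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be strictly positive when present")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclasses.dataclass
class BinaryMask:
    """A {0,1} pixel grid with the same extent as its parent slide."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {px.shape}")
        if px.dtype != bool:
            vals = np.unique(px)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask values must be 0 or 1")
            px = px.astype(bool)
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def matches(self, image: SlideImage) -> bool:
        return (self.height, self.width) == (image.height, image.width)


def _to_rgb(arr: np.ndarray) -> np.ndarray:
    """Promote grayscale to RGB; composite alpha over white."""
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        rgb = arr[..., :3].astype(np.float64)
        alpha = arr[..., 3:4].astype(np.float64) / 255.0
        arr = np.round(rgb * alpha + 255.0 * (1.0 - alpha)).astype(np.uint8)
    elif arr.ndim == 3 and arr.shape[2] == 2:  # gray + alpha
        gray = np.repeat(arr[..., :1], 3, axis=2).astype(np.float64)
        alpha = arr[..., 1:2].astype(np.float64) / 255.0
        arr = np.round(gray * alpha + 255.0 * (1.0 - alpha)).astype(np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"cannot interpret array of shape {arr.shape} as RGB")
    return np.ascontiguousarray(arr, dtype=np.uint8)


def load_image(path: str | Path, pixel_size_um: float | None = None) -> SlideImage:
    """Read a TIFF/PNG/JPEG raster into a :class:`SlideImage`.

    TIFF and PNG decode losslessly; JPEG decodes as stored. Grayscale
    inputs are promoted to RGB by channel replication and alpha channels
    are composited over white (slide scans treat empty area as white).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise FormatError(f"unsupported image format {path.suffix!r}: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                if im.mode not in ("RGB", "RGBA", "L", "LA"):
                    im = im.convert("RGBA" if "A" in im.mode else "RGB")
                arr = np.asarray(im)
    except (UnidentifiedImageError, ValueError, OSError) as exc:
        raise FormatError(f"cannot decode image file: {path} ({exc})") from exc
    if arr.dtype != np.uint8:
        # 16-bit TIFFs are scaled down to 8 bit
        arr = np.round(arr.astype(np.float64) / arr.max() * 255).astype(np.uint8)
    return SlideImage(_to_rgb(arr), pixel_size_um=pixel_size_um, source_id=path.stem)


def save_image(image: SlideImage, path: str | Path) -> Path:
    """Write a slide as lossless PNG or TIFF (chosen by suffix)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels, photometric="rgb")
    elif path.suffix.lower() == ".png":
        Image.fromarray(image.pixels, mode="RGB").save(path, format="PNG")
    else:
        raise FormatError(
            f"artifact images are written as PNG or TIFF only, got {path.suffix!r}"
        )
    return path


def save_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a mask as a single-channel PNG (1 -> 255, 0 -> 0)."""
    path = Path(path)
    if path.suffix.lower() != ".png":
        raise FormatError(f"masks are written as PNG only, got {path.suffix!r}")
    arr = np.where(mask.pixels, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")
    return path


def load_mask(path: str | Path, threshold: int = 128) -> BinaryMask:
    """Read a mask PNG back; grayscale values >= ``threshold`` become 1."""
    slide = load_image(path)
    gray = slide.pixels[..., 0]
    return BinaryMask(gray >= threshold)
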