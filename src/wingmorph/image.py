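"""Image loading and the shared intensity/coordinate conventions.

Every module in the package works on 8-bit grayscale micrographs indexed as
``(row, col)``, 0-based, origin at the top-left.  A pixel occupies unit area
(1 px^2); continuous coordinates (polygon vertices, true trichome centers)
refer to pixel centers, so pixel ``(r, c)`` sits at the continuous point
``(row=r, col=c)``.

Transmitted-light wing micrographs show trichome bases as *slightly darker*
spots on a pale blade, so detection operates on the photometric inverse
(255 - v) where the bases become local maxima; see :mod:`wingmorph.maxima`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = [
    "Micrograph",
    "load_micrograph",
    "save_micrograph",
    "invert",
    "resize",
]

# ITU-R 601 luminance weights, the convention 8-bit microscopy software
# inherited from broadcast video and that ImageJ applies by default.
_LUMA = (0.299, 0.587, 0.114)


@dataclass
class Micrograph:
    """An 8-bit grayscale intensity grid with provenance metadata.

    Parameters
    ----------
    pixels:
        2D array of intensities; any numeric dtype is accepted as long as all
        values lie in [0, 255]; stored as ``uint8``.
    source:
        Free-text provenance, typically a file path or ``"synthetic"``.
    scale_note:
        Optional free text such as a magnification ("200x").
    """

    pixels: np.ndarray
    source: str = "memory"
    scale_note: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise InputError(
                f"micrograph pixels must be a non-empty 2D grid, got shape {arr.shape}"
            )
        if arr.dtype != np.uint8:
            if np.issubdtype(arr.dtype, np.floating) and (
                np.any(~np.isfinite(arr))
            ):
                raise InputError("micrograph pixels contain non-finite values")
            if arr.min() < 0 or arr.max() > 255:
                raise InputError(
                    "micrograph intensities must lie in [0, 255]; got range "
                    f"[{arr.min()}, {arr.max()}]"
                )
            arr = np.round(arr).astype(np.uint8)
        self.pixels = arr

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def copy(self) -> "Micrograph":
        return Micrograph(self.pixels.copy(), self.source, self.scale_note)


def _rgb_to_gray(arr: np.ndarray) -> np.ndarray:
    """ITU-R 601 luminance, rounded half-up to the nearest integer."""
    r, g, b = (arr[..., i].astype(np.float64) for i in range(3))
    lum = _LUMA[0] * r + _LUMA[1] * g + _LUMA[2] * b
    return np.floor(lum + 0.5).astype(np.uint8)


def _rescale_16bit(arr: np.ndarray) -> np.ndarray:
    """Linear per-image min-max rescale of a >8-bit image onto [0, 255]."""
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.floor((arr - lo) / (hi - lo) * 255.0 + 0.5).astype(np.uint8)


def load_micrograph(path: str | os.PathLike) -> Micrograph:
    """Read a TIFF/PNG/JPEG raster as an 8-bit grayscale micrograph.

    RGB(A) input is converted by the 0.299R + 0.587G + 0.114B luminance
    formula (alpha, if present, is ignored); 16-bit input is linearly
    min-max rescaled to [0, 255].
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"no such image file: {path}")
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        else:
            from PIL import Image

            with Image.open(path) as im:
                im.load()
                arr = np.asarray(im)
    except InputError:
        raise
    except Exception as exc:  # corrupt file, unsupported encoding, ...
        raise InputError(f"could not read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise InputError(f"zero-sized image: {path}")
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            arr = arr[..., 0]
        else:
            if arr.dtype != np.uint8:
                arr = _rescale_16bit(arr.reshape(-1, arr.shape[2])).reshape(arr.shape)
            return Micrograph(_rgb_to_gray(arr[..., :3]), source=path)
    if arr.ndim != 2:
        raise InputError(f"unsupported image dimensionality {arr.ndim} in {path}")
    if arr.dtype == np.bool_:
        arr = arr.astype(np.uint8) * 255
    elif arr.dtype != np.uint8:
        arr = _rescale_16bit(arr)
    return Micrograph(arr, source=path)


def save_micrograph(img: Micrograph | np.ndarray, path: str | os.PathLike) -> None:
    """Write an 8-bit grayscale (2D) or RGB (3D uint8) image to TIFF or PNG."""
    arr = img.pixels if isinstance(img, Micrograph) else np.asarray(img, dtype=np.uint8)
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr).save(path)


def invert(img: Micrograph) -> Micrograph:
    """Photometric inversion v -> 255 - v (an involution)."""
    return Micrograph(255 - img.pixels, source=img.source, scale_note=img.scale_note)


def resize(img: Micrograph, out_width: int, out_height: int) -> Micrograph:
    """Bilinear resize to an exact target size (aspect ratio not preserved).

    Downscaling applies a Gaussian prefilter before bilinear sampling so that
    fine texture (trichome dots) is averaged rather than aliased away; output
    is clamped and rounded back onto the 8-bit scale.  Resizing to the source
    dimensions returns a bit-identical copy.
    """
    if out_width < 1 or out_height < 1:
        raise InputError(
            f"target dimensions must be positive, got {out_width}x{out_height}"
        )
    if (out_height, out_width) == img.shape:
        return img.copy()
    from skimage.transform import resize as _sk_resize

    shrink = out_height < img.height or out_width < img.width
    out = _sk_resize(
        img.pixels.astype(np.float64),
        (out_height, out_width),
        order=1,
        mode="edge",
        anti_aliasing=shrink,
        preserve_range=True,
    )
    out = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    return Micrograph(out, source=img.source, scale_note=img.scale_note)
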