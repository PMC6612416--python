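"""Loading raster microscopy images into a normalized multi-channel array.

Images are represented as a :class:`RasterImage` holding a ``(height, width,
n_channels)`` float array with intensities rescaled to ``[0, 1]`` by dividing
by the source dtype's maximum (255 for 8-bit, 65535 for 16-bit).  The dtype
maximum — never a min–max stretch — is used so that intensity ratios between
pixels, which the co-localization statistics depend on, are preserved.

Channel indices in the public API are 1-based, following the convention of
microscopy software where "channel 1" is the first dye.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger("coloc")

SUPPORTED_SUFFIXES = {".jpg", ".jpeg", ".png", ".tif", ".tiff", ".bmp"}


class ImageFormatError(ValueError):
    """The file exists but is not a readable single-frame raster image."""


class UnsupportedDimensionalityError(ImageFormatError):
    """The file contains a 3D stack or a multi-frame/time-series image."""


@dataclass(frozen=True)
class RasterImage:
    """A multi-channel 2D image with intensities in ``[0, 1]``.

    Attributes
    ----------
    pixels
        Array of shape ``(height, width, n_channels)``, float64, in [0, 1].
        Row-major, 0-based internally.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 2:
            px = px[:, :, np.newaxis]
        if px.ndim != 3 or px.shape[0] < 1 or px.shape[1] < 1 or px.shape[2] < 1:
            raise ValueError(f"pixels must be (height, width, n_channels); got shape {np.shape(self.pixels)}")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]


def _normalize(arr: np.ndarray, path: Path) -> np.ndarray:
    """Rescale integer intensities by the dtype maximum; pass floats through."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / float(np.iinfo(arr.dtype).max)
    if np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(np.float64)
        if out.size and (out.min() < 0.0 or out.max() > 1.0):
            raise ImageFormatError(f"float image {path} has intensities outside [0, 1]")
        return out
    raise ImageFormatError(f"unsupported pixel dtype {arr.dtype} in {path}")


def load_image(path: str | Path) -> RasterImage:
    """Read a JPEG/PNG/TIFF/BMP file into a :class:`RasterImage`.

    An alpha channel, if present, is dropped (with a logged warning) before
    construction.  Multi-frame files (z-stacks, time series) are rejected:
    only single-frame 2D images are supported.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    UnsupportedDimensionalityError
        For 3D stacks or multi-frame files.
    ImageFormatError
        For unreadable or unsupported formats.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        # index=None stacks every frame a multi-frame file contains, so
        # stacks/time series show up as an extra leading axis below.
        arr = np.asarray(iio.imread(path, index=None))
    except Exception as exc:  # imageio delegates to plugins with varied error types
        raise ImageFormatError(f"cannot read {path} as a raster image: {exc}") from exc

    if arr.ndim == 2:
        arr = arr[:, :, np.newaxis]
    if arr.ndim == 4 or (arr.ndim == 3 and arr.shape[-1] > 4):
        raise UnsupportedDimensionalityError(
            f"{path} contains a 3D stack or multi-frame image "
            f"(shape {arr.shape}); only single-frame 2D images are supported"
        )
    if arr.ndim != 3:
        raise ImageFormatError(f"cannot interpret {path} with shape {arr.shape}")

    # gray+alpha (2 channels) or RGBA (4 channels): strip the alpha plane
    if arr.shape[-1] in (2, 4):
        logger.warning("dropping alpha channel while loading %s", path)
        arr = arr[:, :, : arr.shape[-1] - 1]

    return RasterImage(_normalize(arr, path))


def get_channel(img: RasterImage, index: int) -> np.ndarray:
    """Return one channel plane (2D array in [0, 1]); ``index`` is 1-based."""
    if not 1 <= index <= img.n_channels:
        raise IndexError(
            f"channel index {index} out of range: image has {img.n_channels} channel(s), valid indices are 1..{img.n_channels}"
        )
    return img.pixels[:, :, index - 1]


def to_grayscale(img: RasterImage) -> np.ndarray:
    """Project to a single plane by the unweighted per-pixel mean of channels.

    Fluorescence channels carry no luminance semantics, so they are averaged
    symmetrically rather than with broadcast-video luma weights.
    """
    return img.pixels.mean(axis=2)
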