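"""Image container, TIFF/PNG input/output and unit-interval rescaling.

All quality markers operate on a 2-D, single-channel, non-negative
intensity array rescaled to [0, 1].  Multichannel files are split into one
:class:`Image` per channel; z-stacks are treated as independent planes.
Pixel intensities are unitless; an optional physical pixel size is carried
as metadata only and never enters any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

#: Minimum number of rows/columns accepted for marker computation.  The
#: Fourier-ring split halves the grid, so anything smaller has no rings.
MIN_SIZE = 8


@dataclass(frozen=True)
class Image:
    """A 2-D grayscale intensity image with an optional background mask.

    Parameters
    ----------
    pixels
        2-D array of finite real intensities.
    background_mask
        Optional boolean array of identical shape; ``True`` marks
        background pixels used for the SNR statistics.
    pixel_size
        Physical length per pixel.  Metadata only.
    image_id
        Identifier used in tables and reports.
    """

    pixels: np.ndarray
    background_mask: np.ndarray | None = None
    pixel_size: float | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.size == 0:
            raise ValueError("pixels must be non-empty")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        object.__setattr__(self, "pixels", px)
        if self.background_mask is not None:
            mask = np.asarray(self.background_mask, dtype=bool)
            if mask.shape != px.shape:
                raise ValueError("background_mask shape must match pixels")
            if not mask.any():
                raise ValueError("background_mask must mark at least one pixel")
            object.__setattr__(self, "background_mask", mask)

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_pix(self) -> int:
        return self.pixels.size

    def with_pixels(self, pixels: np.ndarray) -> "Image":
        """Return a copy with new pixel data, mask and metadata preserved."""
        return replace(self, pixels=pixels)


def require_min_size(arr: np.ndarray | Image) -> None:
    """Reject images too small for marker computation (below 8x8)."""
    px = arr.pixels if isinstance(arr, Image) else arr
    if px.shape[0] < MIN_SIZE or px.shape[1] < MIN_SIZE:
        raise ValueError(
            f"image of shape {px.shape} is below the minimum size "
            f"{MIN_SIZE}x{MIN_SIZE} required for marker computation"
        )


def _split_channels(arr: np.ndarray) -> list[np.ndarray]:
    """Split an array read from disk into a list of 2-D planes.

    Accepts (H, W), (H, W, C) with small C (channel-last) and (C, H, W)
    multi-page layouts.
    """
    if arr.ndim == 2:
        return [arr]
    if arr.ndim == 3:
        # Channel-last (H, W, C) heuristic: trailing axis much smaller.
        if arr.shape[2] <= 4 and arr.shape[0] > 4 and arr.shape[1] > 4:
            return [arr[:, :, c] for c in range(arr.shape[2])]
        return [arr[c] for c in range(arr.shape[0])]
    raise ValueError(f"unsupported image dimensionality: {arr.shape}")


def load_image(
    path: str | Path,
    channel: int | None = None,
    mask_path: str | Path | None = None,
    image_id: str | None = None,
) -> Image | list[Image]:
    """Read a TIFF or PNG file into one :class:`Image` per channel.

    Integer pixel types are converted to floating point without rescaling.
    For a single-channel file, an :class:`Image` is returned; a
    multichannel file yields a list unless ``channel`` selects one plane.

    Parameters
    ----------
    path
        TIFF or PNG file.
    channel
        Zero-based channel index for multichannel files.
    mask_path
        Optional single-channel image of the same size; nonzero pixels
        mark the background region.
    image_id
        Identifier stored on the images; defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = iio.imread(path)
    else:
        raise IOError(f"unsupported image format: {path.suffix!r} (use TIFF or PNG)")
    planes = _split_channels(np.asarray(arr))

    mask = None
    if mask_path is not None:
        mask_arr = load_image(mask_path)
        if isinstance(mask_arr, list):
            raise ValueError("mask must be single-channel")
        mask = mask_arr.pixels > 0

    for p in planes:
        require_min_size(p)
    base_id = image_id if image_id is not None else path.stem
    if channel is not None:
        if not 0 <= channel < len(planes):
            raise IndexError(
                f"channel {channel} out of range for {len(planes)}-channel image"
            )
        return Image(planes[channel], background_mask=mask, image_id=base_id)
    if len(planes) == 1:
        return Image(planes[0], background_mask=mask, image_id=base_id)
    return [
        Image(p, background_mask=mask, image_id=f"{base_id}_c{c}")
        for c, p in enumerate(planes)
    ]


def save_image(img: Image | np.ndarray, path: str | Path) -> None:
    """Write an image as 32-bit float TIFF or 16-bit PNG."""
    path = Path(path)
    px = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=float)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, px.astype(np.float32))
    elif suffix == ".png":
        lo, hi = px.min(), px.max()
        scaled = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo)
        iio.imwrite(path, (scaled * 65535).astype(np.uint16))
    else:
        raise IOError(f"unsupported output format: {path.suffix!r}")


def rescale_unit(img: Image) -> Image:
    """Rescale pixel intensities to the interval [0, 1].

    Applies ``(s - min) / (max - min)`` per image.  A constant image maps
    to all zeros so that batch runs survive blank frames; downstream
    markers then take their degenerate branches.  The mask is carried
    through unchanged.
    """
    px = img.pixels
    lo = px.min()
    hi = px.max()
    if hi == lo:
        return img.with_pixels(np.zeros_like(px))
    return img.with_pixels((px - lo) / (hi - lo))


def as_image(data: Image | np.ndarray, image_id: str = "") -> Image:
    """Coerce a bare array into an :class:`Image`."""
    if isinstance(data, Image):
        return data
    return Image(np.asarray(data, dtype=float), image_id=image_id)
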