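"""Raster I/O for the fusion pipeline.

Reads PNG/TIFF/PGM (8- or 16-bit, grayscale or RGB) into the canonical
[0, 1] float image, resizing to a standard working size, and writes 8-bit
grayscale output.  RGB collapses via Rec. 601 luminance.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .image import as_gray_image

__all__ = ["load_image", "save_image", "resize_bilinear"]

_REC601 = np.array([0.299, 0.587, 0.114])


def resize_bilinear(img: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """Resize a 2-D array to ``target_size`` (rows, cols) bilinearly."""
    rows, cols = target_size
    if rows < 1 or cols < 1:
        raise ValueError(f"target size must be positive, got {target_size}")
    if img.shape == (rows, cols):
        return img.astype(np.float64, copy=True)
    # sample at pixel centres of the target grid mapped into source coords
    r = (np.arange(rows) + 0.5) * img.shape[0] / rows - 0.5
    c = (np.arange(cols) + 0.5) * img.shape[1] / cols - 0.5
    rr, cc = np.meshgrid(r, c, indexing="ij")
    return ndimage.map_coordinates(
        img.astype(np.float64), [rr, cc], order=1, mode="nearest"
    )


def load_image(path: str | Path, target_size: tuple[int, int] | None = (256, 256)) -> np.ndarray:
    """Load a raster file as a [0, 1] gray image.

    Intensities are scaled by the container's bit depth (255 for uint8,
    65535 for uint16); RGB(A) input collapses by Rec. 601 luminance.  With
    ``target_size`` given (default 256x256, the pipeline's standard working
    size) the image is resized bilinearly; pass ``None`` to keep native size.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    arr = iio.imread(path)
    if arr.size == 0:
        raise ValueError(f"zero-area image: {path}")
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        scale = 1.0
    else:
        scale = float(np.iinfo(arr.dtype).max)
    img = arr.astype(np.float64) / scale
    if img.ndim == 3:
        img = img[..., :3] @ _REC601
    if img.ndim != 2:
        raise ValueError(f"cannot interpret {path} (shape {arr.shape}) as grayscale")
    if target_size is not None:
        img = resize_bilinear(img, target_size)
    np.clip(img, 0.0, 1.0, out=img)
    return as_gray_image(img, name=str(path))


def save_image(img: np.ndarray, path: str | Path) -> None:
    """Write a gray image as 8-bit grayscale (values x 255, round half-up).

    Round-tripping through :func:`load_image` (at native size) changes each
    pixel by at most 1/255.
    """
    img = as_gray_image(img)
    # np.round is round-half-even; floor(x+0.5) is the round-half-up contract
    data = np.floor(img * 255.0 + 0.5).astype(np.uint8)
    iio.imwrite(Path(path), data)
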