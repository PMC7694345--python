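"""Grayscale image container conventions and validation.

Every stage of the fusion pipeline operates on a single canonical currency:
a 2-D ``float64`` array of intensities in ``[0, 1]`` ("gray image").
Coordinates are (row, column), 0-based.  This module provides the
validators and the registered-pair container; file I/O lives in
:mod:`sparsefuse.io`.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = ["as_gray_image", "validate_gray_image", "ImagePair"]

#: smallest admissible side length — the 8x8 dictionary atoms and the
#: sliding metric windows are meaningless below this
MIN_SIDE = 8


def validate_gray_image(img: np.ndarray, *, name: str = "image") -> None:
    """Raise ``ValueError`` unless *img* is a valid gray image.

    Valid means: 2-D, finite, values in ``[0, 1]``, both sides >= 8 px.
    """
    if img.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {img.shape}")
    if img.shape[0] < MIN_SIDE or img.shape[1] < MIN_SIDE:
        raise ValueError(f"{name} must be at least {MIN_SIDE}x{MIN_SIDE}, got {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{name} contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError(f"{name} has values outside [0, 1]: range [{img.min()}, {img.max()}]")


def as_gray_image(arr, *, name: str = "image") -> np.ndarray:
    """Coerce *arr* to the canonical float64 gray image and validate it."""
    img = np.asarray(arr, dtype=np.float64)
    validate_gray_image(img, name=name)
    return img


class ImagePair(NamedTuple):
    """A co-registered CT/MRI pair.

    No registration is performed anywhere in the pipeline: the two images
    are assumed to be aligned pixel-for-pixel and must share a shape.
    """

    ct: np.ndarray
    mri: np.ndarray

    def validate(self) -> "ImagePair":
        validate_gray_image(self.ct, name="ct")
        validate_gray_image(self.mri, name="mri")
        if self.ct.shape != self.mri.shape:
            raise ValueError(f"pair shape mismatch: ct {self.ct.shape} vs mri {self.mri.shape}")
        return self
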