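"""Synthetic registered CT-like / MRI-like brain phantom pairs.

Real co-registered CT/MRI pairs are not needed to exercise the pipeline:
this generator emulates the complementary character of the two modalities
on a shared elliptical "skull" geometry.  The CT channel shows a bright
bone ring over a dark background with a low-contrast interior; the MRI
channel shows the same ring dark and a high-contrast textured interior
(smooth tissue blobs, band-limited texture, and a few bright lesions).
The two channels share geometry exactly — they are registered by
construction — and all randomness comes from one explicit seeded
generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import ImagePair, as_gray_image

__all__ = ["PhantomSpec", "make_pair", "degrade"]


@dataclass
class PhantomSpec:
    """Geometry, texture and noise parameters of one phantom pair.

    size
        Side length in pixels (square images), >= 64; 256 is the
        pipeline's standard working size.
    ring_radius / ring_thickness
        Skull-ring outer radius and radial thickness, as fractions of the
        half-size.
    texture_amplitude
        Amplitude of the band-limited interior texture in the MRI channel.
    noise_sigma
        Additive Gaussian noise level on both channels.
    lesion_count
        Number of small bright lesions in the MRI interior.
    """

    size: int = 256
    seed: int = 0
    ring_radius: float = 0.78
    ring_thickness: float = 0.14
    texture_amplitude: float = 0.25
    noise_sigma: float = 0.01
    lesion_count: int = 3

    def validate(self) -> "PhantomSpec":
        if self.size < 64:
            raise ValueError("phantom size must be >= 64")
        if not (0 < self.ring_radius < 1) or not (0 < self.ring_thickness < 1):
            raise ValueError("ring fractions must lie in (0, 1)")
        if self.noise_sigma < 0 or self.texture_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.lesion_count < 0:
            raise ValueError("lesion_count must be >= 0")
        return self


def _elliptical_rho(size: int) -> np.ndarray:
    """Normalised elliptical radius: 1 at the nominal head boundary."""
    c = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size]
    return np.sqrt(((y - c) / c) ** 2 + ((x - c) / (0.85 * c)) ** 2)


def _smooth_blobs(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=sigma, mode="wrap")
    return field / (np.abs(field).max() + 1e-12)


def make_pair(spec: PhantomSpec | None = None) -> ImagePair:
    """Generate one registered CT-like / MRI-like pair, deterministically
    for a given spec (including its seed)."""
    spec = (spec or PhantomSpec()).validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    rho = _elliptical_rho(size)
    r_out = spec.ring_radius
    r_in = r_out - spec.ring_thickness
    ring = (rho >= r_in) & (rho < r_out)
    interior = rho < r_in

    # CT: bright bone ring, subdued interior with faint smooth structure
    ct = np.full((size, size), 0.05)
    ct[ring] = 0.9
    ct_interior = 0.35 + 0.05 * _smooth_blobs(rng, size, sigma=size / 16)
    ct[interior] = ct_interior[interior]

    # MRI: dark ring, busy interior: smooth tissue + band-limited texture
    mri = np.full((size, size), 0.05)
    mri[ring] = 0.15
    tissue = 0.45 + 0.2 * _smooth_blobs(rng, size, sigma=size / 24)
    noise = rng.standard_normal((size, size))
    band = ndimage.gaussian_filter(noise, 1.0, mode="wrap") - ndimage.gaussian_filter(
        noise, 3.0, mode="wrap"
    )
    band /= np.abs(band).max() + 1e-12
    mri_interior = tissue + spec.texture_amplitude * band
    mri[interior] = mri_interior[interior]

    # lesions: small bright discs well inside the interior, MRI-visible
    c = (size - 1) / 2.0
    for _ in range(spec.lesion_count):
        while True:
            ly, lx = rng.uniform(0.15 * size, 0.85 * size, size=2)
            if _elliptical_rho(size)[int(ly), int(lx)] < 0.6 * r_in:
                break
        radius = rng.uniform(0.015, 0.03) * size
        y, x = np.mgrid[0:size, 0:size]
        disc = (y - ly) ** 2 + (x - lx) ** 2 < radius**2
        mri[disc] = np.clip(mri[disc] + 0.3, None, 1.0)

    if spec.noise_sigma > 0:
        ct = ct + spec.noise_sigma * rng.standard_normal((size, size))
        mri = mri + spec.noise_sigma * rng.standard_normal((size, size))
    ct = np.clip(ct, 0.0, 1.0)
    mri = np.clip(mri, 0.0, 1.0)
    return ImagePair(ct=ct, mri=mri).validate()


def degrade(img: np.ndarray, kind: str, amount: float, seed: int = 0) -> np.ndarray:
    """Controlled degradations for metric monotonicity checks.

    ``blur``: Gaussian blur with sigma = amount; ``noise``: additive
    Gaussian noise with sigma = amount; ``contrast-loss``: linear
    compression toward the mean, amount 1 collapsing to the constant mean.
    Amount 0 is always the identity.
    """
    img = as_gray_image(img)
    if amount < 0:
        raise ValueError("amount must be >= 0")
    if amount == 0:
        return img.copy()
    if kind == "blur":
        out = ndimage.gaussian_filter(img, sigma=amount, mode="reflect")
    elif kind == "noise":
        rng = np.random.default_rng(seed)
        out = img + amount * rng.standard_normal(img.shape)
    elif kind == "contrast-loss":
        a = min(amount, 1.0)
        out = img.mean() + (1.0 - a) * (img - img.mean())
    else:
        raise ValueError(f"unknown degradation kind {kind!r}")
    return np.clip(out, 0.0, 1.0)
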