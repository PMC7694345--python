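"""Objective fusion-quality metrics.

Five reference-free fusion metrics, each comparing the fused image ``f``
against the two source images ``a`` (CT) and ``b`` (MRI):

* **MI** — summed mutual information I(a;f) + I(b;f) from 256-level joint
  histograms (bits).
* **EN** — Shannon entropy of the fused image over 256 gray levels (bits).
* **FMI** — feature mutual information: windowed mutual information between
  Sobel gradient-magnitude features of the fused and source images,
  normalised per window by the marginal feature entropies, in [0, 1].
* **Qabf** — the Xydeas-Petrovic edge-transfer measure: per-pixel edge
  strength/orientation preservation mapped through sigmoids and averaged
  with gradient-strength weights, in [0, 1].
* **VIF** — pixel-domain multi-scale visual information fidelity
  (Gaussian scale mixture model), averaged over the two sources.

Degenerate inputs (constant images, zero gradients) are given explicit
conventional values rather than NaNs; see each function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import convolve2d
from scipy.signal.windows import gaussian as gaussian_window

from .gradient import sobel_gradients
from .image import as_gray_image

__all__ = [
    "MetricReport",
    "quantize",
    "mutual_information",
    "entropy",
    "fmi",
    "qabf",
    "vif",
    "vif_average",
    "evaluate_pair",
]

# Xydeas-Petrovic sigmoid constants (strength / orientation)
QABF_GAMMA_G = 0.9994
QABF_K_G = -15.0
QABF_SIGMA_G = 0.5
QABF_GAMMA_A = 0.9879
QABF_K_A = -22.0
QABF_SIGMA_A = 0.8

VIF_SIGMA_NSQ = 2.0


def quantize(img: np.ndarray, n_levels: int = 256) -> np.ndarray:
    """Quantize a [0,1] image onto integer levels 0..n_levels-1 by
    ``floor(v * (n_levels - 1) + 0.5)``."""
    img = as_gray_image(img)
    return np.floor(img * (n_levels - 1) + 0.5).astype(np.intp)


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum() + 0.0)  # +0.0 normalizes -0.0


def entropy(f: np.ndarray, n_levels: int = 256) -> float:
    """Shannon entropy (bits) of the quantized intensity histogram."""
    levels = quantize(f, n_levels)
    return _entropy_from_counts(np.bincount(levels.ravel(), minlength=n_levels))


def _mi_pair(x: np.ndarray, y: np.ndarray, n_levels: int) -> float:
    joint, _, _ = np.histogram2d(
        x.ravel(), y.ravel(), bins=n_levels, range=[[0, n_levels], [0, n_levels]]
    )
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    return float((pxy[nz] * np.log2(pxy[nz] / np.outer(px, py)[nz])).sum())


def mutual_information(
    a: np.ndarray, b: np.ndarray, f: np.ndarray, n_levels: int = 256
) -> float:
    """MI = I(a; f) + I(b; f) in bits (0 log 0 := 0)."""
    qa, qb, qf = (quantize(x, n_levels) for x in (a, b, f))
    if qa.shape != qf.shape or qb.shape != qf.shape:
        raise ValueError("images must share a shape")
    return _mi_pair(qa, qf, n_levels) + _mi_pair(qb, qf, n_levels)


# ---------------------------------------------------------------------------
# FMI


def _window_views(arr: np.ndarray, w: int) -> np.ndarray:
    """(n_windows, w*w) view of all stride-1 w x w windows."""
    v = np.lib.stride_tricks.sliding_window_view(arr, (w, w))
    return v.reshape(-1, w * w)


def _binary_entropy(p1: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p1)
    for p in (p1, 1.0 - p1):
        nz = p > 0
        out[nz] -= p[nz] * np.log2(p[nz])
    return out


def _binary_mi(n_joint: np.ndarray, n: int) -> np.ndarray:
    """Empirical MI (bits) of two binary variables from the 2x2 joint
    counts ``n_joint`` of shape (n_windows, 2, 2)."""
    p = n_joint / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    ratio = np.divide(p, px * py, out=np.ones_like(p), where=(p > 0))
    terms = np.where(p > 0, p * np.log2(ratio), 0.0)
    return terms.sum(axis=(1, 2))


def _joint_counts(bm: np.ndarray, bi: np.ndarray) -> np.ndarray:
    n11 = (bm & bi).sum(axis=1)
    n10 = (bm & ~bi).sum(axis=1)
    n01 = (~bm & bi).sum(axis=1)
    n00 = (~bm & ~bi).sum(axis=1)
    return np.stack(
        [np.stack([n00, n01], axis=-1), np.stack([n10, n11], axis=-1)], axis=1
    ).astype(np.float64)


def fmi(a: np.ndarray, b: np.ndarray, f: np.ndarray, window: int = 3) -> float:
    """Feature mutual information of the fused image against both sources.

    Features are Sobel gradient magnitudes.  Over every stride-1
    ``window x window`` patch, each feature patch is binarized at its own
    mean and the empirical mutual information ``I`` and marginal entropies
    ``S`` of the binary features are accumulated as
    ``I(m,i)/(S_m + S_i) + I(m,j)/(S_m + S_j)``, averaged over the windows
    where both denominators are positive.  Identical inputs score exactly
    1 (``I(x;x) = S(x)``); if no window is informative (e.g. constant
    images with zero gradients everywhere) the score is 0.
    """
    a, b, f = (as_gray_image(x) for x in (a, b, f))
    if not (a.shape == b.shape == f.shape):
        raise ValueError("images must share a shape")
    if window > min(f.shape):
        raise ValueError("window larger than the image")
    feats = [sobel_gradients(x).magnitude for x in (a, b, f)]
    wa, wb, wm = (_window_views(x, window) for x in feats)
    n = window * window
    binar = [w > w.mean(axis=1, keepdims=True) for w in (wa, wb, wm)]
    ba, bb, bm = binar
    s = [_binary_entropy(x.mean(axis=1)) for x in binar]
    s_a, s_b, s_m = s
    i_ma = _binary_mi(_joint_counts(bm, ba), n)
    i_mb = _binary_mi(_joint_counts(bm, bb), n)
    den_a = s_m + s_a
    den_b = s_m + s_b
    valid = (den_a > 0) & (den_b > 0)
    if not valid.any():
        return 0.0
    score = i_ma[valid] / den_a[valid] + i_mb[valid] / den_b[valid]
    return float(score.mean())


# ---------------------------------------------------------------------------
# Qabf


def _strength_orientation(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = sobel_gradients(img)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(g.gx != 0, g.gy / np.where(g.gx != 0, g.gx, 1.0), 0.0)
    alpha = np.where(g.gx != 0, np.arctan(ratio), np.pi / 2)
    return g.magnitude, alpha


def _preservation(gs: np.ndarray, als: np.ndarray, gf: np.ndarray, alf: np.ndarray) -> np.ndarray:
    """Per-pixel edge preservation Q of one source in the fused image."""
    with np.errstate(divide="ignore", invalid="ignore"):
        G = np.where(
            gs > gf,
            np.divide(gf, gs, out=np.zeros_like(gf), where=gs > 0),
            np.divide(gs, gf, out=np.zeros_like(gs), where=gf > 0),
        )
    A = 1.0 - np.abs(als - alf) / (np.pi / 2)
    qg = QABF_GAMMA_G / (1.0 + np.exp(QABF_K_G * (G - QABF_SIGMA_G)))
    qa = QABF_GAMMA_A / (1.0 + np.exp(QABF_K_A * (A - QABF_SIGMA_A)))
    q = qg * qa
    # conventions: an edge wholly absent from the fused image counts 0, and
    # pixels with no source edge carry no information to preserve; the tiny
    # tolerance absorbs convolution round-off on flat regions
    tol = 1e-10
    q = np.where((gf <= tol) & (gs > tol), 0.0, q)
    q = np.where(gs <= tol, 0.0, q)
    return q


def qabf(a: np.ndarray, b: np.ndarray, f: np.ndarray, T: float = 1.0) -> float:
    """Xydeas-Petrovic edge-transfer quality in [0, 1].

    Gradient-strength weights ``W = g**T``; returns 0 when neither source
    has any edge energy, and exactly 0 for a constant fused image.
    """
    a, b, f = (as_gray_image(x) for x in (a, b, f))
    if not (a.shape == b.shape == f.shape):
        raise ValueError("images must share a shape")
    ga, ala = _strength_orientation(a)
    gb, alb = _strength_orientation(b)
    gf, alf = _strength_orientation(f)
    q_af = _preservation(ga, ala, gf, alf)
    q_bf = _preservation(gb, alb, gf, alf)
    wa = ga**T
    wb = gb**T
    den = float((wa + wb).sum())
    if den == 0.0:
        return 0.0
    return float((q_af * wa + q_bf * wb).sum() / den)


# ---------------------------------------------------------------------------
# VIF (pixel domain, multi-scale)


def _gauss_kernel(n: int) -> np.ndarray:
    g = gaussian_window(n, n / 5.0)
    k = np.outer(g, g)
    return k / k.sum()


def vif(ref: np.ndarray, dist: np.ndarray) -> float:
    """Pixel-domain multi-scale visual information fidelity of ``dist``
    with respect to ``ref`` (scalar Gaussian-scale-mixture model, 4 scales,
    noise variance 2).  Identical images score 1; scales whose Gaussian
    window no longer fits the (downsampled) image are skipped; a reference
    with no information at any usable scale scores 1 by convention.
    """
    ref = np.asarray(ref, dtype=np.float64)
    dist = np.asarray(dist, dtype=np.float64)
    if ref.shape != dist.shape:
        raise ValueError("images must share a shape")
    num = den = 0.0
    r, d = ref, dist
    for scale in range(1, 5):
        n = 2 ** (4 - scale + 1) + 1
        if min(r.shape) < n:
            break
        win = _gauss_kernel(n)
        if scale > 1:
            r = convolve2d(r, win, mode="valid")[::2, ::2]
            d = convolve2d(d, win, mode="valid")[::2, ::2]
            if min(r.shape) < n:
                break
        mu1 = convolve2d(r, win, mode="valid")
        mu2 = convolve2d(d, win, mode="valid")
        mu1_sq, mu2_sq, mu1_mu2 = mu1 * mu1, mu2 * mu2, mu1 * mu2
        sigma1_sq = convolve2d(r * r, win, mode="valid") - mu1_sq
        sigma2_sq = convolve2d(d * d, win, mode="valid") - mu2_sq
        sigma12 = convolve2d(r * d, win, mode="valid") - mu1_mu2
        sigma1_sq = np.maximum(sigma1_sq, 0.0)
        sigma2_sq = np.maximum(sigma2_sq, 0.0)
        g = np.divide(
            sigma12, sigma1_sq + 1e-10, out=np.zeros_like(sigma12), where=sigma1_sq > 1e-10
        )
        sv_sq = sigma2_sq - g * sigma12
        g = np.where(sigma1_sq < 1e-10, 0.0, g)
        sv_sq = np.where(sigma1_sq < 1e-10, sigma2_sq, sv_sq)
        sigma1 = np.where(sigma1_sq < 1e-10, 0.0, sigma1_sq)
        sv_sq = np.where(g < 0, sigma2_sq, sv_sq)
        g = np.maximum(g, 0.0)
        sv_sq = np.maximum(sv_sq, 1e-10)
        num += float(np.log10(1.0 + g * g * sigma1 / (sv_sq + VIF_SIGMA_NSQ)).sum())
        den += float(np.log10(1.0 + sigma1 / VIF_SIGMA_NSQ).sum())
    if den == 0.0:
        return 1.0
    return num / den


def vif_average(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> float:
    """Mean of VIF(a, f) and VIF(b, f)."""
    a, b, f = (as_gray_image(x) for x in (a, b, f))
    return 0.5 * (vif(a, f) + vif(b, f))


# ---------------------------------------------------------------------------
# report


@dataclass
class MetricReport:
    """The five fusion scores; ``flags`` names metrics that hit a
    degenerate-input convention (constant image, zero gradients)."""

    mi: float
    en: float
    fmi: float
    qabf: float
    vif: float
    flags: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict[str, float]:
        return {
            "MI": self.mi,
            "EN": self.en,
            "FMI": self.fmi,
            "Qabf": self.qabf,
            "VIF": self.vif,
        }


def evaluate_pair(
    a: np.ndarray, b: np.ndarray, f: np.ndarray, n_levels: int = 256, fmi_window: int = 3
) -> MetricReport:
    """Compute all five metrics for a fused image against its sources."""
    a, b, f = (as_gray_image(x) for x in (a, b, f))
    flags = []
    if f.max() == f.min():
        flags.append("constant_fused")
    ga = sobel_gradients(a).magnitude
    gb = sobel_gradients(b).magnitude
    if ga.max() == 0 and gb.max() == 0:
        flags.append("zero_source_gradients")
    return MetricReport(
        mi=mutual_information(a, b, f, n_levels),
        en=entropy(f, n_levels),
        fmi=fmi(a, b, f, fmi_window),
        qabf=qabf(a, b, f),
        vif=vif_average(a, b, f),
        flags=tuple(flags),
    )
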