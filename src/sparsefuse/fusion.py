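"""Activity-map fusion and the end-to-end pipeline.

The fusion rule operates on the sparse coefficient stacks of the two
sources: per pixel, the *activity* of a component is the l1 norm of its
coefficient vector across filters; activities are window-averaged for
robustness to noise and slight misregistration; the *choose-max* rule then
copies, per pixel and per component, the whole coefficient vector from the
source with the larger smoothed activity.  The fused image is the linear
synthesis of the fused cartoon and texture stacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import FusionConfig, PipelineConfig
from .csc import (
    CoefficientStack,
    FilterBank,
    _bank_fft,
    build_dictionary,
    csc_solve,
    expand_by_residual_similarity,
    fft_conv_sum,
)
from .enhance import enhance
from .image import ImagePair, as_gray_image

__all__ = [
    "ActivityMap",
    "activity_map",
    "smooth_activity",
    "choose_max",
    "reconstruct",
    "fuse",
    "FusionResult",
]


@dataclass
class ActivityMap:
    """Raw (zeta) and window-smoothed (zeta_tilde) activity of one
    component of one source; ``smoothed`` is None until smoothing runs."""

    component: str
    raw: np.ndarray
    smoothed: np.ndarray | None = None


def activity_map(stack: CoefficientStack) -> ActivityMap:
    """Per-pixel l1 activity: ``zeta(p,q) = sum_u |phi_u(p,q)|``."""
    stack.validate()
    return ActivityMap(component=stack.component, raw=np.abs(stack.maps).sum(axis=0))


def smooth_activity(m: ActivityMap, half_width: int) -> ActivityMap:
    """Window-average the raw activity over a (2m+1)^2 neighbourhood with
    symmetric border padding; ``half_width = 0`` is the identity."""
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    size = 2 * half_width + 1
    smoothed = ndimage.uniform_filter(m.raw, size=size, mode="reflect")
    return ActivityMap(component=m.component, raw=m.raw, smoothed=smoothed)


def choose_max(
    stacks_by_source: tuple[CoefficientStack, CoefficientStack],
    activities: tuple[ActivityMap, ActivityMap],
    cfg: FusionConfig | None = None,
) -> CoefficientStack:
    """Choose-max rule: per pixel take the whole coefficient vector of the
    source with the larger smoothed activity (ties to ``cfg.tie_break``)."""
    cfg = cfg or FusionConfig()
    cfg.validate()
    if len(stacks_by_source) != 2 or len(activities) != 2:
        raise ValueError("fusion is pairwise: exactly two sources required")
    s0, s1 = (s.validate() for s in stacks_by_source)
    if s0.maps.shape != s1.maps.shape or s0.component != s1.component:
        raise ValueError("source stacks must share component and shape")
    a0, a1 = activities
    z0 = a0.smoothed if a0.smoothed is not None else a0.raw
    z1 = a1.smoothed if a1.smoothed is not None else a1.raw
    if cfg.tie_break == 0:
        take_second = z1 > z0
    else:
        take_second = z1 >= z0
    fused = np.where(take_second[None], s1.maps, s0.maps)
    return CoefficientStack(s0.component, fused).validate()


def reconstruct(
    fused_c: CoefficientStack,
    fused_t: CoefficientStack,
    bank: FilterBank,
) -> np.ndarray:
    """Synthesise the fused image from the fused stacks and clip to [0,1]."""
    bank.validate()
    shape = fused_c.maps.shape[1:]
    out = fft_conv_sum(fused_c.maps, _bank_fft(bank.cartoon, shape), shape)
    out += fft_conv_sum(fused_t.maps, _bank_fft(bank.texture, shape), shape)
    return np.clip(out, 0.0, 1.0)


@dataclass
class FusionResult:
    """Fused image plus the exportable intermediates of both sources."""

    fused: np.ndarray
    enhanced: tuple[np.ndarray, np.ndarray]
    cartoon: tuple[np.ndarray, np.ndarray]
    texture: tuple[np.ndarray, np.ndarray]


def fuse(
    pair: ImagePair,
    cfg: PipelineConfig | None = None,
    *,
    return_intermediates: bool = False,
):
    """Run the full fusion pipeline on a registered CT/MRI pair.

    enhance both sources -> decompose each into cartoon/texture coefficient
    stacks -> l1 activity + window smoothing per component -> choose-max
    per component -> synthesise and clip.  Fully deterministic for a given
    configuration.
    """
    cfg = (cfg or PipelineConfig()).validate()
    pair = ImagePair(as_gray_image(pair.ct, name="ct"), as_gray_image(pair.mri, name="mri"))
    pair.validate()
    bank = build_dictionary(cfg.csc)

    enhanced = [enhance(img, cfg.enhancement) for img in pair]
    stacks = []  # per source: (stack_c, stack_t)
    for img in enhanced:
        sc, st, _ = csc_solve(img, bank, cfg.csc)
        sc, st = expand_by_residual_similarity(img, (sc, st), bank, cfg.csc)
        stacks.append((sc, st))

    fused_stacks = {}
    for j, half_width in (("c", cfg.fusion.m_cartoon), ("t", cfg.fusion.m_texture)):
        idx = 0 if j == "c" else 1
        comp_stacks = (stacks[0][idx], stacks[1][idx])
        acts = tuple(
            smooth_activity(activity_map(s), half_width) for s in comp_stacks
        )
        fused_stacks[j] = choose_max(comp_stacks, acts, cfg.fusion)

    fused = reconstruct(fused_stacks["c"], fused_stacks["t"], bank)
    if not return_intermediates:
        return fused
    shape = fused.shape
    fc = _bank_fft(bank.cartoon, shape)
    ft = _bank_fft(bank.texture, shape)
    cartoons = tuple(fft_conv_sum(s[0].maps, fc, shape) for s in stacks)
    textures = tuple(fft_conv_sum(s[1].maps, ft, shape) for s in stacks)
    return FusionResult(
        fused=fused,
        enhanced=tuple(enhanced),
        cartoon=cartoons,
        texture=textures,
    )
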