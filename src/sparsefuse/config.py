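"""Pipeline configuration.

Collects every tunable of the fusion pipeline in one serialisable place:
contrast-enhancement parameters, convolutional-sparse-coding (CSC) solver
parameters, fusion-rule windows, and metric parameters.  All defaults are
the package's study conditions; they can be overridden from a YAML file
(see :func:`PipelineConfig.from_yaml`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "EnhancementConfig",
    "CSCConfig",
    "FusionConfig",
    "MetricConfig",
    "PipelineConfig",
]


@dataclass
class EnhancementConfig:
    """Illumination-guided contrast enhancement parameters.

    phi
        Exponent controlling the degree of enhancement: the blend weight is
        ``W = A**phi`` where ``A`` is the illumination map.
    smoothing
        Coefficient of the edge-aware smoothness prior in the illumination
        solve (larger -> flatter illumination map).
    kappa
        Guard added to the windowed-gradient magnitude in the edge-aware
        weights, bounding them by ``1/kappa``.
    eps
        Guard in the smoothness denominators and the positivity clamp of
        the brightness estimate.
    window
        Half-width (pixels) of the directional neighbourhood over which
        gradients are summed when forming the edge-aware weights.
    """

    phi: float = 0.5
    smoothing: float = 1e-3
    kappa: float = 1e-3
    eps: float = 1e-3
    window: int = 2

    def validate(self) -> None:
        if self.phi <= 0 or self.smoothing <= 0:
            raise ValueError("phi and smoothing must be positive")
        if not (0 < self.kappa <= 1e-2) or not (0 < self.eps <= 1e-2):
            raise ValueError("kappa and eps must lie in (0, 1e-2]")
        if self.window < 0:
            raise ValueError("window must be >= 0")


@dataclass
class CSCConfig:
    """Convolutional sparse coding solver parameters.

    nu_cartoon / nu_texture
        l1 sparsity weights of the cartoon and texture coefficient maps.
    rho
        ADMM penalty parameter.
    max_inner
        Cap on ADMM iterations per block subproblem.
    max_outer
        Cap on cartoon/texture block alternations.
    tol
        Convergence tolerance, used both for the ADMM primal/dual residuals
        and for the relative objective change across block alternations.
    tau
        Residual-correlation similarity threshold in [0, 1] for the
        coefficient-expansion step (1 disables expansion).
    kernel_size, n_cartoon, n_texture
        Dictionary geometry: s x s DCT atoms, split into the n_cartoon
        lowest-frequency (cartoon) and n_texture highest-frequency,
        zero-mean (texture) atoms.
    taper
        Border width (pixels) of the cosine edge taper applied before the
        periodic-boundary frequency-domain solve; 0 disables.
    """

    nu_cartoon: float = 0.01
    nu_texture: float = 0.005
    rho: float = 1.0
    max_inner: int = 100
    max_outer: int = 10
    tol: float = 1e-4
    tau: float = 0.8
    kernel_size: int = 8
    n_cartoon: int = 8
    n_texture: int = 16
    taper: int = 4

    def validate(self) -> None:
        if self.nu_cartoon < 0 or self.nu_texture < 0:
            raise ValueError("sparsity weights must be >= 0")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError("tau must lie in [0, 1]")
        if self.n_cartoon < 1 or self.n_texture < 1:
            raise ValueError("need at least one cartoon and one texture atom")
        if self.n_cartoon + self.n_texture > self.kernel_size**2:
            raise ValueError("dictionary larger than the DCT basis")


@dataclass
class FusionConfig:
    """Choose-max fusion parameters.

    m_cartoon / m_texture are the half-widths of the activity-smoothing
    windows for the two components (cartoon smoother than texture);
    tie_break names the source that wins equal activities (0 = CT).
    """

    m_cartoon: int = 2
    m_texture: int = 1
    tie_break: int = 0

    def validate(self) -> None:
        if self.m_cartoon < 0 or self.m_texture < 0:
            raise ValueError("window half-widths must be >= 0")
        if self.tie_break not in (0, 1):
            raise ValueError("tie_break must be 0 or 1")


@dataclass
class MetricConfig:
    """Quality-metric parameters: gray levels and the FMI window."""

    n_levels: int = 256
    fmi_window: int = 3

    def validate(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.fmi_window < 2 or self.fmi_window % 2 == 0:
            raise ValueError("fmi_window must be odd and >= 3")


@dataclass
class PipelineConfig:
    """Full pipeline configuration with a reproducibility seed."""

    enhancement: EnhancementConfig = field(default_factory=EnhancementConfig)
    csc: CSCConfig = field(default_factory=CSCConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    metrics: MetricConfig = field(default_factory=MetricConfig)
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        self.enhancement.validate()
        self.csc.validate()
        self.fusion.validate()
        self.metrics.validate()
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        for section in ("enhancement", "csc", "fusion", "metrics"):
            sub = d.get(section, {})
            obj = getattr(cfg, section)
            for k, v in sub.items():
                if not hasattr(obj, k):
                    raise KeyError(f"unknown {section} option {k!r}")
                setattr(obj, k, v)
        if "seed" in d:
            cfg.seed = int(d["seed"])
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
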