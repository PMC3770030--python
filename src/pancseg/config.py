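"""Pipeline configuration: grouped parameters with load-time validation.

Groups mirror the pipeline stages.  Note two unrelated (alpha, beta)
pairs exist: ``sigmoid.alpha/beta`` shape the speed map's sigmoid, while
``tune.alpha/beta`` weight the energy-tune enhancement/decay.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .mdrls import MdrlsParams

__all__ = [
    "PreprocessConfig",
    "SigmoidConfig",
    "EnergyConfig",
    "FastMarchingConfig",
    "PostprocessConfig",
    "PipelineConfig",
]


@dataclass(frozen=True)
class PreprocessConfig:
    conductance: float = 10.0
    time_step: float = 0.125
    n_iters: int = 10
    sigma: float = 1.0  # Gaussian-derivative width for gradient maps (px)

    def __post_init__(self):
        if self.conductance <= 0:
            raise ValueError("preprocess.conductance must be positive")
        if not 0 < self.time_step <= 0.25:
            raise ValueError("preprocess.time_step must satisfy 0 < t <= 0.25")
        if self.n_iters < 0:
            raise ValueError("preprocess.n_iters must be non-negative")
        if self.sigma <= 0:
            raise ValueError("preprocess.sigma must be positive")


@dataclass(frozen=True)
class SigmoidConfig:
    alpha: float = -0.5
    beta: float = 3.0
    out_min: float = 0.0
    out_max: float = 1.0

    def __post_init__(self):
        if self.alpha == 0:
            raise ValueError("sigmoid.alpha must be nonzero")
        if not self.out_min < self.out_max:
            raise ValueError("sigmoid.out_min must be < sigmoid.out_max")


@dataclass(frozen=True)
class EnergyConfig:
    sigma: float = 10.0  # decay length of the source-energy kernel (px)
    t_d: float = 3.0  # energy-decrement band half-width around the line (px)
    d_t: float = 15.0  # attenuation-band width of the automatic tune (px)
    tune_alpha: float = 1.0
    tune_beta: float = 1.0
    boundary_only: bool = False  # opt-in source restriction to R0's boundary
    enable_tune: bool = True  # False: level set runs on the raw edge map

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("energy.sigma must be positive")
        if self.t_d < 0:
            raise ValueError("energy.t_d must be non-negative")
        if self.d_t <= 0:
            raise ValueError("energy.d_t must be positive")


@dataclass(frozen=True)
class FastMarchingConfig:
    t_star: float = 100.0  # front-snapshot time threshold (time units)

    def __post_init__(self):
        if self.t_star < 0:
            raise ValueError("fm.t_star must be non-negative")


@dataclass(frozen=True)
class PostprocessConfig:
    radius: int = 2
    min_component: int = 20

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("post.radius must be >= 1")
        if self.min_component < 1:
            raise ValueError("post.min_component must be >= 1")


_GROUPS = {
    "preprocess": PreprocessConfig,
    "sigmoid": SigmoidConfig,
    "energy": EnergyConfig,
    "fm": FastMarchingConfig,
    "mdrls": MdrlsParams,
    "post": PostprocessConfig,
}


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sigmoid: SigmoidConfig = field(default_factory=SigmoidConfig)
    energy: EnergyConfig = field(default_factory=EnergyConfig)
    fm: FastMarchingConfig = field(default_factory=FastMarchingConfig)
    mdrls: MdrlsParams = field(default_factory=MdrlsParams)
    post: PostprocessConfig = field(default_factory=PostprocessConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build from nested dicts; unknown groups or keys are rejected."""
        kwargs = {}
        for group, sub in data.items():
            if group not in _GROUPS:
                raise ValueError(f"unknown config group '{group}' (expected one of {sorted(_GROUPS)})")
            gcls = _GROUPS[group]
            known = {f.name for f in dataclasses.fields(gcls)}
            bad = set(sub) - known
            if bad:
                raise ValueError(f"unknown key(s) {sorted(bad)} in config group '{group}'")
            kwargs[group] = gcls(**sub)
        return cls(**kwargs)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_dict(self) -> dict:
        return {g: dataclasses.asdict(getattr(self, g)) for g in _GROUPS}

    def to_toml(self, path) -> None:
        """Write the fully resolved configuration for reproducibility."""
        lines = []
        for group, sub in self.to_dict().items():
            lines.append(f"[{group}]")
            for key, val in sub.items():
                if isinstance(val, bool):
                    lines.append(f"{key} = {'true' if val else 'false'}")
                else:
                    lines.append(f"{key} = {val}")
            lines.append("")
        Path(path).write_text("\n".join(lines))
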