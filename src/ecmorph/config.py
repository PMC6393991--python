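"""Run configuration: validated TOML with sections for each pipeline stage.

Unknown sections or keys are rejected rather than ignored, so a typo in a
config file cannot silently fall back to a default threshold.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

from .degradation import StructuringElement
from .errors import ValidationError
from .fractal import FractalConfig
from .segmentation import SegmentationConfig


@dataclass(frozen=True)
class TissueConfig:
    whiteness_threshold: int = 220
    min_channel_spread: int = 30
    close_holes: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.whiteness_threshold <= 255:
            raise ValidationError("whiteness_threshold must lie in [0, 255]")
        if not 0 <= self.min_channel_spread <= 255:
            raise ValidationError("min_channel_spread must lie in [0, 255]")


@dataclass(frozen=True)
class ErosionConfig:
    shape: str = "square3"
    max_cycles: int = 100_000

    def __post_init__(self) -> None:
        StructuringElement(self.shape)  # validates
        if self.max_cycles < 1:
            raise ValidationError("max_cycles must be >= 1")

    def element(self) -> StructuringElement:
        return StructuringElement(self.shape)


@dataclass(frozen=True)
class StatsConfig:
    welch: bool = False
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    tissue: TissueConfig = field(default_factory=TissueConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    fractal: FractalConfig = field(default_factory=FractalConfig)
    erosion: ErosionConfig = field(default_factory=ErosionConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0


_SECTIONS = {
    "tissue": TissueConfig,
    "segmentation": SegmentationConfig,
    "fractal": FractalConfig,
    "erosion": ErosionConfig,
    "stats": StatsConfig,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} in config section [{section}]"
        )
    if cls is FractalConfig and "epsilons" in data:
        data = {**data, "epsilons": tuple(int(e) for e in data["epsilons"])}
    return cls(**data)


def load_run_config(path: "str | Path | None" = None) -> RunConfig:
    """Load a RunConfig from TOML; a missing path returns pure defaults."""
    if path is None:
        return RunConfig()
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    seed = raw.pop("seed", 0)
    if not isinstance(seed, int):
        raise ValidationError("seed must be an integer")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValidationError(f"unknown config section(s): {sorted(unknown)}")
    sections = {
        name: _build_section(cls, raw.get(name, {}), name)
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(seed=seed, **sections)
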