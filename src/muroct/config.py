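"""Pipeline configuration: one YAML file mirrors one :class:`PipelineConfig`."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .thickness import QCParams
from .unet import ModelConfig

__all__ = ["CohortConfig", "StatsConfig", "SegmentationConfig", "PipelineConfig"]


@dataclass
class CohortConfig:
    """What to simulate: groups, imaging ages, animals per group, volume shape."""

    groups: list = field(default_factory=lambda: ["WT", "3xTg-AD"])
    ages: list = field(default_factory=lambda: [1, 2, 3, 4])
    n_animals: int = 4
    # (n_bscans, n_ascans, n_samples); trimmed lateral dims must divide by 3
    shape: tuple = (32, 128, 256)
    speckle_sigma: float = 0.2

    def __post_init__(self) -> None:
        self.shape = tuple(self.shape)
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not self.ages:
            raise ValueError("age list must not be empty")


@dataclass
class StatsConfig:
    normality_alpha: float = 0.10
    # the eight layers compared at each time point form the Bonferroni family;
    # TRT is tested on its own
    bonferroni_m: int = 8
    alpha_levels: tuple = (0.05, 0.01, 0.001)

    def __post_init__(self) -> None:
        if not 0 < self.normality_alpha < 1:
            raise ValueError("normality_alpha must lie in (0, 1)")
        if self.bonferroni_m < 1:
            raise ValueError("bonferroni_m must be >= 1")


@dataclass
class SegmentationConfig:
    mode: str = "oracle"  # 'oracle' (ground-truth class maps) or 'network'
    checkpoint: str | None = None  # required for mode='network'
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("oracle", "network"):
            raise ValueError("segmentation mode must be 'oracle' or 'network'")


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; all randomness flows from ``seed``."""

    seed: int = 0
    out_dir: str = "muroct_out"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    qc: QCParams = field(default_factory=QCParams)
    stats: StatsConfig = field(default_factory=StatsConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    abnormality_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.abnormality_alpha < 1:
            raise ValueError("abnormality_alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        if "cohort" in kw:
            kw["cohort"] = CohortConfig(**kw["cohort"])
        if "qc" in kw:
            kw["qc"] = QCParams(**kw["qc"])
        if "stats" in kw:
            s = dict(kw["stats"])
            if "alpha_levels" in s:
                s["alpha_levels"] = tuple(s["alpha_levels"])
            kw["stats"] = StatsConfig(**s)
        if "segmentation" in kw:
            s = dict(kw["segmentation"])
            if "model" in s:
                s["model"] = ModelConfig(**s["model"])
            kw["segmentation"] = SegmentationConfig(**s)
        return cls(**kw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["cohort"]["shape"] = list(self.cohort.shape)
        d["stats"]["alpha_levels"] = list(self.stats.alpha_levels)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
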