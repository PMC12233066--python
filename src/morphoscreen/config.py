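"""Run configuration: YAML loading, schema validation, provenance hashing."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import Field, ValidationError, model_validator

from ._model import StrictModel, config_hash
from .classify import ClassifierConfig
from .profiling import ProfilingConfig
from .segment import SegmentationConfig
from .synth import SyntheticSpec


class ConfigError(ValueError):
    """Raised when a configuration file fails schema validation."""


class AnalysisOptions(StrictModel):
    standardize: bool = True
    umap: bool = False
    figure: bool = False
    umap_n_neighbors: int = Field(default=15, ge=2)


class ConditionSpec(StrictModel):
    """One experimental condition: a name plus its generative parameters."""

    name: str
    replicates: int = Field(default=3, ge=1)
    synth: SyntheticSpec = Field(default_factory=SyntheticSpec)


class RunConfig(StrictModel):
    """Full end-to-end pipeline configuration.

    ``calibration_um_per_px`` defaults to the synthetic pixel size of the
    first condition so descriptor magnitudes stay physically consistent.
    """

    seed: int = 0
    calibration_um_per_px: float | None = Field(default=None, gt=0)
    conditions: list[ConditionSpec]
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    profiling: ProfilingConfig = Field(default_factory=ProfilingConfig)
    classifier: ClassifierConfig | None = None
    analysis: AnalysisOptions = Field(default_factory=AnalysisOptions)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not self.conditions:
            raise ValueError("at least one condition is required")
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate condition names: {names}")
        return self

    @property
    def calibration(self) -> float:
        if self.calibration_um_per_px is not None:
            return self.calibration_um_per_px
        return self.conditions[0].synth.pixel_size

    @property
    def hash(self) -> str:
        return config_hash(self)


def _format_validation_error(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        lines.append(f"  {loc}: {e['msg']}")
    return "invalid configuration:\n" + "\n".join(lines)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys anywhere in the document are rejected; the error message
    lists every offending key/field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig(**data)
    except ValidationError as err:
        raise ConfigError(_format_validation_error(err)) from err


def load_stage_config(path: str | Path, model: type[StrictModel]) -> StrictModel:
    """Load a single stage's YAML config (e.g. just a SegmentationConfig)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return model(**data)
    except ValidationError as err:
        raise ConfigError(_format_validation_error(err)) from err


def demo_config_path() -> Path:
    """Path to the bundled end-to-end demo configuration."""
    return Path(__file__).parent / "data" / "demo.yaml"


def demo_config() -> RunConfig:
    return load_config(demo_config_path())
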