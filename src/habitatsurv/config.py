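"""Run configuration: YAML in, validated settings out.

The schema is a pydantic model; every violation is reported with a dotted
path into the config (e.g. ``phantom.noise_sd``).  Omitted fields take the
package defaults, so an empty file is a valid configuration.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from .radiomics import N_FEATURES


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every violation."""

    def __init__(self, errors: List[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


class PhantomSection(BaseModel):
    n_short: int = Field(default=16, ge=0)
    n_long: int = Field(default=13, ge=0)
    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: multiplier applied to every map's default voxel-noise SD
    noise_sd: float = Field(default=1.0, ge=0)

    @field_validator("voxel_size")
    @classmethod
    def _positive_voxels(cls, v):
        if any(x <= 0 for x in v):
            raise ValueError("voxel_size entries must be > 0")
        return v


class SegmentationSection(BaseModel):
    slicewise: bool = False
    n_init: int = Field(default=10, ge=1)


class RadiomicsSection(BaseModel):
    n_levels: int = Field(default=32, ge=2)


class SelectionSection(BaseModel):
    enabled: bool = True
    n_select: int = Field(default=60, ge=1, le=N_FEATURES)
    step_fraction: float = Field(default=0.1, gt=0, le=1)
    n_trees: int = Field(default=200, ge=1)


class EvaluationSection(BaseModel):
    trials: int = Field(default=10, ge=1)
    n_estimators: int = Field(default=100, ge=1)
    learning_rate: float = Field(default=0.1, gt=0, le=1)
    max_depth: int = Field(default=2, ge=1)
    subsample: float = Field(default=1.0, gt=0, le=1)
    tune: bool = False
    paper_faithful: bool = False
    threshold: float = Field(default=0.5, gt=0, lt=1)


class RunConfig(BaseModel):
    seed: int = 0
    out: str = "runs/run"
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    segmentation: SegmentationSection = Field(
        default_factory=SegmentationSection)
    radiomics: RadiomicsSection = Field(default_factory=RadiomicsSection)
    selection: SelectionSection = Field(default_factory=SelectionSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)


def _format_errors(err: ValidationError) -> List[str]:
    out = []
    for e in err.errors():
        path = ".".join(str(p) for p in e["loc"]) or "<root>"
        out.append(f"{path}: {e['msg']}")
    return out


def config_from_dict(data: Optional[Dict]) -> RunConfig:
    try:
        return RunConfig(**(data or {}))
    except ValidationError as err:
        raise ConfigError(_format_errors(err)) from err


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty (or missing-keys) file yields the defaults; any violation
    raises :class:`ConfigError` naming each offending field.
    """
    p = Path(path)
    if not p.exists():
        raise ConfigError([f"config file not found: {p}"])
    try:
        data = yaml.safe_load(p.read_text())
    except yaml.YAMLError as err:
        raise ConfigError([f"unreadable YAML: {err}"]) from err
    if data is not None and not isinstance(data, dict):
        raise ConfigError(["top level of the config must be a mapping"])
    return config_from_dict(data)
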