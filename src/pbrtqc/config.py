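"""Pipeline configuration: analytes, candidate grids, seeds, block size."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, Field, model_validator

from .ma import (
    DEFAULT_BATCH_SIZES,
    DEFAULT_WEIGHTING_FACTORS,
    MAConfig,
    TruncationLimits,
)
from .profiles import CLIA_TEA_PERCENT, AnalyteProfile, builtin_profiles

__all__ = [
    "AnalyteConfig",
    "PipelineConfig",
    "load_config",
    "config_hash",
    "default_candidates",
    "default_pipeline_config",
]

#: truncation-limit candidates screened per packaged analyte, alongside the
#: no-truncation baseline
_TRUNCATION_CANDIDATES: dict[str, list[TruncationLimits]] = {
    "creatinine": [TruncationLimits(upper=u) for u in (150, 200, 300, 400)],
    "sodium": [
        TruncationLimits(upper=145),
        TruncationLimits(lower=130, upper=145),
    ],
    "potassium": [TruncationLimits(upper=6.0)],
    "albumin": [TruncationLimits(lower=30)],
}


def default_candidates(analyte: Optional[str] = None) -> list[MAConfig]:
    """The full screening grid for one analyte.

    Five simple-MA batch sizes and four EWMA weighting factors, each
    without truncation and with every truncation candidate known for the
    analyte (none for analytes outside the packaged four).
    """
    variants = [TruncationLimits()] + _TRUNCATION_CANDIDATES.get(analyte or "", [])
    grid: list[MAConfig] = []
    for trunc in variants:
        for n in DEFAULT_BATCH_SIZES:
            grid.append(MAConfig(algorithm="simple", batch_size=n, truncation=trunc))
        for lam in DEFAULT_WEIGHTING_FACTORS:
            grid.append(MAConfig(algorithm="ewma", weighting_factor=lam, truncation=trunc))
    return grid


class AnalyteConfig(BaseModel):
    """One analyte's inputs: a profile to synthesise from or a stream file."""

    name: str
    profile: Optional[AnalyteProfile] = None
    stream_file: Optional[str] = None
    tea_percent: float = Field(gt=0.0)
    daily_volume: Optional[int] = Field(default=None, ge=1)
    candidates: Optional[list[MAConfig]] = None

    @model_validator(mode="after")
    def _has_source(self) -> "AnalyteConfig":
        if self.profile is None and self.stream_file is None:
            raise ValueError(
                f"analyte {self.name!r} needs either a profile or a stream_file"
            )
        return self

    def resolved_daily_volume(self) -> int:
        if self.daily_volume is not None:
            return self.daily_volume
        if self.profile is not None:
            return self.profile.daily_volume
        raise ValueError(
            f"analyte {self.name!r} has no profile; set daily_volume explicitly"
        )

    def resolved_candidates(self) -> list[MAConfig]:
        return self.candidates if self.candidates else default_candidates(self.name)


class PipelineConfig(BaseModel):
    analytes: list[AnalyteConfig]
    seed: int = 1
    n_days: int = Field(default=121, ge=1)
    block: int = Field(default=400, ge=2)

    @model_validator(mode="after")
    def _nonempty(self) -> "PipelineConfig":
        if not self.analytes:
            raise ValueError("pipeline config lists no analytes")
        return self


def default_pipeline_config(seed: int = 1, n_days: int = 121) -> PipelineConfig:
    """Packaged four-analyte configuration with the full candidate grids."""
    return PipelineConfig(
        analytes=[
            AnalyteConfig(name=name, profile=prof, tea_percent=CLIA_TEA_PERCENT[name])
            for name, prof in builtin_profiles().items()
        ],
        seed=seed,
        n_days=n_days,
    )


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Load a YAML or JSON pipeline configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PipelineConfig.model_validate(data)


def config_hash(config: PipelineConfig) -> str:
    """Short stable digest of a configuration, for output provenance."""
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha1(canonical.encode()).hexdigest()[:12]
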