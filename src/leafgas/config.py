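"""Declarative run configuration (YAML) for the command-line interface.

A single config file carries what flags handle poorly: per-file metadata
(species/genotype group, individual id, leaf width, stomatal density), the
chamber geometry, the light schedule and the analysis options.  Schema
violations are reported with field paths.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import ConfigurationError


class FileEntry(BaseModel):
    path: str
    individual: str
    group: str = "all"
    leaf_width_cm: float = Field(gt=0)
    stomatal_density_mm2: Optional[float] = Field(default=None, gt=0)
    allow_oversize: bool = False


class Chamber(BaseModel):
    area_cm2: float = Field(gt=0)
    diameter_cm: float = Field(gt=0)


class ScheduleStep(BaseModel):
    par: float = Field(ge=0)
    duration_min: float = Field(gt=0)


class AnalysisOptions(BaseModel):
    steady_window_s: float = Field(default=300.0, gt=0)
    normalization: Literal["absolute", "relative", "per_stoma"] = "absolute"
    reference_phase: str = "high_light_1"
    gsw_floor: float = Field(default=1e-3, gt=0)
    response_floor: float = Field(default=0.01, ge=0)
    outlier_iqr_factor: float = Field(default=1.5, ge=0)


class RunConfig(BaseModel):
    files: list[FileEntry] = Field(min_length=1)
    chamber: Chamber
    schedule: Optional[list[ScheduleStep]] = None
    detect_phases: bool = False
    analysis: AnalysisOptions = AnalysisOptions()
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.schedule is None and not self.detect_phases:
            raise ValueError("either schedule or detect_phases: true is required")
        if self.analysis.normalization == "per_stoma":
            missing = [f.individual for f in self.files if f.stomatal_density_mm2 is None]
            if missing:
                raise ValueError(
                    f"per_stoma normalization requires stomatal_density_mm2 for every file; "
                    f"missing for individuals {missing}"
                )
        return self

    def schedule_tuples(self) -> list[tuple[float, float]] | None:
        if self.schedule is None:
            return None
        return [(s.par, s.duration_min * 60.0) for s in self.schedule]


class GsmaxModelSpec(BaseModel):
    name: str
    coefficients: dict[str, float]


class GsmaxSpec(BaseModel):
    amax_model: GsmaxModelSpec
    pore_depth_model: GsmaxModelSpec
    d_w: float = Field(default=2.49e-5, gt=0)
    v: float = Field(default=0.0224, gt=0)


class AnatomyConfig(BaseModel):
    counts_csv: str
    measurements_csv: str
    group_map: dict[str, str] = Field(default_factory=dict)  # individual -> group
    gsmax: Optional[GsmaxSpec] = None
    gsw_high_light: dict[str, float] = Field(default_factory=dict)  # group -> gsw for opening %


def _load(path: str | Path, model):
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    payload = yaml.safe_load(path.read_text()) or {}
    try:
        cfg = model.model_validate(payload)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigurationError("invalid config:\n" + "\n".join(lines)) from exc
    return cfg


def load_run_config(path: str | Path) -> RunConfig:
    cfg = _load(path, RunConfig)
    base = Path(path).parent
    for f in cfg.files:
        p = Path(f.path)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise ConfigurationError(f"files: data file does not resolve: {f.path}")
        f.path = str(p)
    return cfg


def load_anatomy_config(path: str | Path) -> AnatomyConfig:
    cfg = _load(path, AnatomyConfig)
    base = Path(path).parent
    for attr in ("counts_csv", "measurements_csv"):
        p = Path(getattr(cfg, attr))
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise ConfigurationError(f"{attr}: data file does not resolve: {getattr(cfg, attr)}")
        setattr(cfg, attr, str(p))
    return cfg
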