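"""Pipeline configuration: one YAML-loadable object holding every constant.

Defaults mirror the analysis constants: thresholds 5.7/6.5 %, a 90-day
baseline window, minimum two distinct HbA1C test dates, 2.5 % trimmed from
each interval tail, and 365 days per year for conversions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, ValidationError

from .errors import ConfigError


class PipelineConfig(BaseModel):
    labs_path: Path
    prescriptions_path: Path
    patients_path: Path
    druglist_path: Path
    output_dir: Path

    threshold_lower: float = 5.7
    threshold_upper: float = 6.5
    window_days: int = Field(default=90, ge=0)
    min_tests: int = Field(default=2, ge=2)
    trim_fraction: float = Field(default=0.025, ge=0.0, lt=0.5)
    days_per_year: float = Field(default=365.0, gt=0)
    lower_boundary_group: Literal["low", "increased"] = "increased"
    upper_boundary_group: Literal["increased", "diabetes"] = "diabetes"
    drop_nonpositive_slopes: bool = True
    trim_scope: Literal["pooled", "per_group"] = "pooled"
    validate_study_window: bool = False
    seed: int = 0

    @classmethod
    def build(cls, **kwargs) -> "PipelineConfig":
        try:
            return cls(**kwargs)
        except ValidationError as exc:
            first = exc.errors()[0]
            loc = ".".join(str(p) for p in first["loc"]) or "config"
            raise ConfigError(f"{loc}: {first['msg']}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.build(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = {k: (str(v) if isinstance(v, Path) else v) for k, v in self.model_dump().items()}
        path.write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")
        return path

    def check_inputs(self) -> "PipelineConfig":
        for name in ("labs_path", "prescriptions_path", "patients_path", "druglist_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"{name}: file not found: {p}")
        if not self.threshold_lower < self.threshold_upper:
            raise ConfigError("threshold_lower: must be strictly below threshold_upper")
        return self
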