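"""Pipeline configuration.

A single :class:`PipelineConfig` collects the knobs of the analysis chain:
the quantile convention for the per-center month-1 quartiles, the
majority threshold of the clinical-FIS rule, the locus-filter thresholds
of the association screen, and the direction map used by the genetic-EIP
refinement.  Configs load from YAML or JSON; unspecified fields keep their
defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .types import ValidationError


@dataclass
class LociFilterConfig:
    """Thresholds of the training-phase locus filter."""

    p_threshold: float = 0.05
    consecutive_weeks_min: int = 2
    maf_min: float = 0.1
    ld_r2_max: float = 0.5
    replication_weeks_min: int = 1

    def validate(self) -> None:
        for name in ("p_threshold", "maf_min", "ld_r2_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name}={v} outside (0, 1)")
        if self.consecutive_weeks_min < 1 or self.replication_weeks_min < 1:
            raise ValidationError("week-count thresholds must be >= 1")


@dataclass
class PipelineConfig:
    quartile_method: str = "linear"
    weeks_required_majority: int = 3
    fis_window_days: int = 28
    loci_filter: LociFilterConfig = field(default_factory=LociFilterConfig)
    #: per-locus map rsid -> {"slow": [genotypes], "fast": [genotypes]}
    minor_direction: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    welch: bool = True
    alpha_to_enter: float = 0.05

    def validate(self) -> None:
        if self.weeks_required_majority < 1 or self.weeks_required_majority > 4:
            raise ValidationError("weeks_required_majority must be in [1, 4]")
        if not 0.0 < self.alpha_to_enter < 1.0:
            raise ValidationError("alpha_to_enter outside (0, 1)")
        self.loci_filter.validate()


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML or JSON."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    data = data or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    if "loci_filter" in data:
        data["loci_filter"] = LociFilterConfig(**data["loci_filter"])
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg
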