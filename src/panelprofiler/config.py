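"""Pipeline configuration loaded from YAML.

Unknown keys are rejected so that typos fail loudly rather than silently
falling back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ValidationError
from .variants import CallerParams


@dataclass
class MSIParams:
    alpha: float = 0.001
    top_k: int = 30
    score_threshold: float = 0.4
    both_sided: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("msi.alpha must lie in (0,1)")
        if self.top_k < 1:
            raise ValidationError("msi.top_k must be >= 1")
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ValidationError("msi.score_threshold must lie in [0,1]")


@dataclass
class TMBParams:
    region_size_mb: float = 2.2
    cutoff: float = 10.0

    def __post_init__(self) -> None:
        if self.region_size_mb <= 0:
            raise ValidationError("tmb.region_size_mb must be > 0")
        if self.cutoff < 0:
            raise ValidationError("tmb.cutoff must be >= 0")


@dataclass
class StatsParams:
    merge_jejunum_ileum: bool = False
    alpha: float = 0.05
    adjust: bool = True
    welch: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("stats.alpha must lie in (0,1)")


@dataclass
class PipelineConfig:
    caller: CallerParams = field(default_factory=CallerParams)
    msi: MSIParams = field(default_factory=MSIParams)
    tmb: TMBParams = field(default_factory=TMBParams)
    stats: StatsParams = field(default_factory=StatsParams)
    seed: int = 0
    log_level: str = "INFO"


_SECTIONS = {
    "caller": CallerParams,
    "msi": MSIParams,
    "tmb": TMBParams,
    "stats": StatsParams,
}


def _build(cls, mapping: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValidationError(
            f"unknown key(s) in config section {section!r}: "
            f"{', '.join(sorted(unknown))}"
        )
    return cls(**mapping)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a pipeline config from YAML; None yields all defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"seed", "log_level"}
    if unknown:
        raise ValidationError(
            f"{path}: unknown top-level config key(s): {', '.join(sorted(unknown))}"
        )
    kwargs = {
        name: _build(cls, raw.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    return PipelineConfig(
        **kwargs,
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
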