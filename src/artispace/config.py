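"""Run configuration: dataclass bundle, YAML round-trip, and config hash."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .audio import PreprocessConfig
from .sms import SMSConfig

__all__ = ["AnalysisConfig", "ModelConfig", "load_config", "config_hash"]


@dataclass
class ModelConfig:
    """Mixed-model options: contrast coding, confidence level, and an
    optional constraint fixing the pair-intercept variance (``var_pair=0``
    profiles the random effect out, reducing the fit to OLS/GLS)."""

    coding: str = "simple"  # or "treatment"
    ci_level: float = 0.95
    var_pair: float | None = None


@dataclass
class AnalysisConfig:
    """Everything that influences the numbers a run produces.

    The config hash stamped on every output is derived from these fields
    alone, so it changes iff an analysis-relevant parameter changes.
    """

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sms: SMSConfig = field(default_factory=SMSConfig)
    contour: "ContourConfig" = None  # type: ignore[assignment]
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        from .contour import ContourConfig

        if self.contour is None:
            self.contour = ContourConfig()

    def to_dict(self) -> dict:
        return {
            "preprocess": dataclasses.asdict(self.preprocess),
            "sms": dataclasses.asdict(self.sms),
            "contour": dataclasses.asdict(self.contour),
            "model": dataclasses.asdict(self.model),
            "seed": self.seed,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Build an AnalysisConfig from a YAML file; missing blocks keep defaults."""
    from .contour import ContourConfig

    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    return AnalysisConfig(
        preprocess=PreprocessConfig(**raw.get("preprocess", {})),
        sms=SMSConfig(**raw.get("sms", {})),
        contour=ContourConfig(**raw.get("contour", {})),
        model=ModelConfig(**raw.get("model", {})),
        seed=int(raw.get("seed", 0)),
    )


def config_hash(config: AnalysisConfig) -> str:
    """Short stable digest of the analysis-relevant configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
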