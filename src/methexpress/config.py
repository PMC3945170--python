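"""Pipeline configuration: thresholds, paths, contrast, optional simulation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["Thresholds", "Contrast", "PipelineConfig"]


@dataclass
class Thresholds:
    """Every decision threshold of the pipeline, with its default."""

    det_p: float = 0.01          # detection p-value below which a probe is present
    min_present: int | None = None  # presence quorum; None -> ceil(5/6 * group)
    delta_beta: float = 0.15     # strict |Δβ| threshold for DM calling
    de_alpha: float = 0.05       # BH-adjusted p threshold for DE
    anova_alpha: float = 0.05    # BH-adjusted p threshold for the interaction
    shore_bp: int = 4000         # CGI flank width defining the merged shore

    def __post_init__(self) -> None:
        if not (0 < self.det_p < 1):
            raise ValueError("det_p must be in (0, 1)")
        if not (0 < self.delta_beta <= 1):
            raise ValueError("delta_beta must be in (0, 1]")
        for name in ("de_alpha", "anova_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.shore_bp < 0:
            raise ValueError("shore_bp must be nonnegative")
        if self.min_present is not None and self.min_present < 1:
            raise ValueError("min_present must be positive")


@dataclass
class Contrast:
    case: str = "OSIS"
    control: str = "EIUM"
    treatment: str | None = None

    @property
    def label(self) -> str:
        arm = f"_{self.treatment}" if self.treatment else ""
        return f"{self.case}_vs_{self.control}{arm}"


@dataclass
class PipelineConfig:
    """Structured configuration consumed by :func:`methexpress.pipeline.run_all`."""

    out_dir: Path = Path("methexpress_out")
    seed: int = 0
    paths: dict = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    contrast: Contrast = field(default_factory=Contrast)
    simulate: dict | None = None
    background_size: int | None = None  # ORA universe; None -> annotated genes

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls(
            out_dir=Path(raw.get("out_dir", "methexpress_out")),
            seed=int(raw.get("seed", 0)),
            paths={k: Path(v) for k, v in (raw.get("paths") or {}).items()},
            thresholds=Thresholds(**(raw.get("thresholds") or {})),
            contrast=Contrast(**(raw.get("contrast") or {})),
            simulate=raw.get("simulate"),
            background_size=raw.get("background_size"),
        )
        return cfg

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "paths": {k: str(v) for k, v in self.paths.items()},
            "thresholds": vars(self.thresholds).copy(),
            "contrast": vars(self.contrast).copy(),
            "simulate": self.simulate,
            "background_size": self.background_size,
        }

    def write_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
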