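"""Pipeline configuration: defaults, file loading (YAML/TOML), validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .errors import ValidationError


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; all fields have safe defaults.

    ``profiles`` and ``effects`` are optional override mappings merged onto
    the generator defaults (see :mod:`circalipid.synth`); statistical options
    cover the FDR level, the BH family layout and metric computation flags.
    """

    seed: int = 0
    n_subjects: int = 27
    seasons: Sequence[str] = ("WS", "SE", "SS")
    n_days: int = 7
    melatonin_fraction: float = 13.0 / 27.0
    fdr: float = 0.1
    bh_family: str = "global"            # or "per_outcome"
    epoch_min: int = 30
    metric_basis: str = "composite"      # or "per_day"
    log_light: bool = False              # log10(x+1) before cosinor fitting
    profiles: Optional[dict] = None      # season -> SeasonProfile field overrides
    effects: Optional[dict] = None       # outcome -> predictor -> beta
    residual_sd: Optional[dict] = None
    lipid_scales: Optional[dict] = None
    rhythm_outcomes: Sequence[str] = ("hdl", "tg")

    def validate(self) -> "PipelineConfig":
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        if not 0 < self.fdr < 1:
            raise ValidationError(f"FDR {self.fdr} outside (0, 1)")
        if self.bh_family not in ("global", "per_outcome"):
            raise ValidationError(f"unknown bh_family {self.bh_family!r}")
        if self.metric_basis not in ("composite", "per_day"):
            raise ValidationError(f"unknown metric_basis {self.metric_basis!r}")
        if 1440 % self.epoch_min != 0:
            raise ValidationError(
                f"epoch_min {self.epoch_min} does not divide 1440")
        if not 0 <= self.melatonin_fraction <= 1:
            raise ValidationError("melatonin_fraction outside [0, 1]")
        bad = [s for s in self.seasons if s not in ("WS", "SE", "SS")]
        if bad:
            raise ValidationError(f"unknown season label(s) {bad}")
        if self.n_days < 3:
            raise ValidationError("need >= 3 recording days per season")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text) or {}
        elif path.suffix == ".toml":
            import tomllib
            data = tomllib.loads(text)
        else:
            raise ValidationError(f"unsupported config format {path.suffix!r}")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data).validate()

    def canonical_json(self) -> str:
        data = asdict(self)
        data["seasons"] = list(self.seasons)
        data["rhythm_outcomes"] = list(self.rhythm_outcomes)
        return json.dumps(data, sort_keys=True, separators=(",", ":"))

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()
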