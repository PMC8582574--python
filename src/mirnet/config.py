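"""Pipeline configuration: presets, YAML loading, provenance hashing."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .io import ValidationError

__all__ = ["PipelineConfig", "PRESETS"]

# (rho_max, min_degree) presets: tumor data shows weaker correlations than
# cell lines, so the tumor preset pairs a looser correlation threshold with
# a lower core-degree cutoff.
PRESETS: dict[str, tuple[float, int]] = {
    "tumor": (-0.4, 20),
    "cell-line": (-0.6, 100),
}


@dataclass
class PipelineConfig:
    """All thresholds and paths for a pipeline run.

    ``mode`` selects a named preset for (rho_max, min_degree); "custom"
    requires both explicitly. All preset values can be overridden.
    """

    mode: str = "tumor"
    rho_max: float | None = None
    min_degree: int | None = None
    plot_min_degree: int = 15
    min_purity: float = 0.80
    q_cutoff: float = 0.05
    top_k: int = 10
    endpoint: str = "os"
    seed: int = 0
    keep_equal_degree: bool = False
    data_dir: str = "data"
    out_dir: str = "results"
    mirna_path: str | None = None
    mrna_path: str | None = None
    annotation_path: str | None = None
    cohort_counts_path: str | None = None
    gmt_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in (*PRESETS, "custom"):
            raise ValidationError(f"mode must be one of {[*PRESETS, 'custom']}")
        if self.mode != "custom":
            preset_rho, preset_deg = PRESETS[self.mode]
            if self.rho_max is None:
                self.rho_max = preset_rho
            if self.min_degree is None:
                self.min_degree = preset_deg
        if self.rho_max is None or self.min_degree is None:
            raise ValidationError("custom mode requires rho_max and min_degree")
        if not self.rho_max < 0:
            raise ValidationError("rho_max must be negative")
        if self.min_degree < 0:
            raise ValidationError("min_degree must be >= 0")
        if not 0.0 <= self.min_purity <= 1.0:
            raise ValidationError("min_purity must be in [0, 1]")
        if not 0.0 < self.q_cutoff <= 1.0:
            raise ValidationError("q_cutoff must be in (0, 1]")
        if self.endpoint not in ("pfs", "os"):
            raise ValidationError("endpoint must be 'pfs' or 'os'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for provenance."""
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
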