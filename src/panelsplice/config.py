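"""Pipeline configuration: every threshold in one place.

Defaults follow the published analysis conventions where one exists (junction
pre-filter 5 reads; novel-junction minimum 10 reads and 10% of the overlapping
canonical junction; ALT depth >= 10; ASE nulls 0.45 left / 0.5 right) and the
package's documented inferred defaults elsewhere (rarity cutoff 0.02, TraP
probably-damaging boundary 0.93, retention and usage-outlier rules).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # junction stage
    min_reads_prefilter: int = 5
    min_junction_reads: int = 10
    min_junction_fraction: float = 0.10
    canonical_reference_mode: str = "max"  # or "sum"
    # intron retention
    usage_ratio_threshold: float = 0.8
    retention_min_coverage: float = 5.0
    retention_rel_flank: float = 0.10
    # PSI / usage
    psi_flank_mode: str = "mean"  # or "sum"
    usage_z_threshold: float = 3.0
    usage_min_fold: float = 1.6
    # ASE / NMD
    ase_null_left: float = 0.45
    ase_null_right: float = 0.50
    ase_alpha: float = 0.05
    min_alt_reads: int = 10
    expression_z_normal: float = 2.0
    # variant prioritization
    max_af: float = 0.02
    trap_min: float = 0.93
    link_window_bp: int = 10

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls().to_dict())
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
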