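"""Pipeline configuration: every threshold the analyses use, with defaults
equal to the study's stated values (pseudocount beta = 0.001, dips <= 0.4
over >= 50 bp, CpG coverage > 5 reads, Bonferroni alpha = 0.05, 2% cell
fraction thresholds, 0.25 fold-change filter, 2 kb promoters, 5 kb TSS
windows)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .simulate import SimulationConfig


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    beta: float = 0.001
    min_coverage: int = 5
    dip_max_ml: float = 0.4
    dip_min_len_bp: int = 50
    dip_window_bp: int = 10
    alpha: float = 0.05
    correction: str = "BH"
    min_pct: float = 0.02
    de_min_abs_log2fc: float | None = 0.25
    new_peak_threshold: float = 0.02
    fisher_bin_bp: int = 1000
    promoter_width: int = 2000
    tss_window_bp: int = 5000
    strict_enhancer: bool = False
    deconv_top_fraction: float = 1.0
    deconv_min_markers: int = 5
    deconv_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        # one seed drives both the generator and every pipeline draw
        self.simulation.seed = self.seed

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
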