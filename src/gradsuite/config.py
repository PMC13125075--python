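"""Run configuration: a fully serializable description of one analysis.

A run directory always contains the resolved configuration that produced
it, so every number in the report can be regenerated from the config and
the input files alone.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import FormatError


@dataclass
class QCConfig:
    fd_mm: float = 0.2              # framewise-displacement flag threshold (mm)
    dvars_sd: float = 3.0           # standardized-DVARS flag threshold
    min_template_r: float = 0.4     # alignment-QC: minimum r with template gradient


@dataclass
class StatsConfig:
    tails: str = "two-sided"            # for the Fisher r-to-z comparison
    family_size_regions: int | None = None        # Bonferroni family, 2-way cells
    family_size_network_regions: int | None = None  # 3-way cells
    greenhouse_geisser: bool = True


@dataclass
class EmbeddingSettings:
    n_components_whole_brain: int = 10
    n_components_insula: int = 3
    alpha: float = 0.5
    diffusion_time: float = 0.0
    sparsity: float = 0.10


@dataclass
class RunConfig:
    """Everything a full analysis run needs."""

    parcellation: str = "parcellation.csv"
    subdivisions: str | None = "insula_subdivisions.csv"
    matrices_dir: str = "matrices"
    subject_table: str = "subjects.csv"
    output_dir: str = "run"
    embedding: EmbeddingSettings = field(default_factory=EmbeddingSettings)
    qc: QCConfig = field(default_factory=QCConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    insula_pattern: str = "SalVentAttn_FrOperIns"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a mapping")
        for key, sub in (("embedding", EmbeddingSettings),
                         ("qc", QCConfig), ("stats", StatsConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
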