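"""Pipeline configuration.

Defaults follow the study parameters where stated: k = 21 with count
retention bounds ci = 1, cs = 10000 for k-mer counting, and a 500 bp minimum
contig length. Configuration files are YAML; unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # k-mer parameters
    k: int = 21
    ci: int = 1
    cs: int = 10000
    min_pair_cov: int = 4
    # binning
    min_contig_len: int = 500
    seed_len: int = 31
    # ploidy caller
    q_max: int = 8
    ratio_tol: float = 0.03
    cov_tol: float = 0.25
    parsimony_margin: float = 0.05
    ambiguity_margin: float = 0.05
    # per-stage seeds
    seeds: dict = field(default_factory=lambda: {
        "genome": 0, "genes": 1, "coverage": 2, "reads": 3, "contamination": 4, "ogtable": 5})
    # synthetic run shape (used by the `report` pipeline)
    genome_length: int = 60000
    ploidy: int = 2
    het_rate: float = 0.01
    haploid_coverage: float = 25.0
    n_genes: int = 10

    def __post_init__(self) -> None:
        if self.k % 2 == 0:
            raise ConfigError(f"k must be odd, got {self.k}")
        if self.ci < 1 or self.cs < self.ci:
            raise ConfigError("need 1 <= ci <= cs")
        if self.min_contig_len < 0 or self.seed_len < 1:
            raise ConfigError("min_contig_len must be >= 0 and seed_len >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
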