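"""Pipeline configuration: every survey threshold in one validated object."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from exrte.insertion_age import DEFAULT_RATE, RECENT_BOUNDARY_YEARS


@dataclass
class PipelineConfig:
    """Thresholds of the survey, with the published defaults.

    acm_cutoff None means "derive from the reference genes"; set a number
    (e.g. 1.7) to fix it.
    """

    min_rte_length: int = 500
    required_domains: tuple[str, ...] = ("GAG", "AP", "INT", "RT", "RH")
    rpkm_min: float = 0.25
    cov_min: float = 0.60
    min_domain_aa: int = 50
    dedup_identity: float = 0.95
    strict_same_sample: bool = False
    pooled_coverage: bool = False
    min_orf_nt: int = 300
    mutation_rate: float = DEFAULT_RATE
    recent_boundary_years: float = RECENT_BOUNDARY_YEARS
    close_gene_bp: int = 1000
    acm_cutoff: float | None = None
    group1_min_cultivars: int = 2
    seed: int = 0
    domain_tags: dict[str, str] | None = None  # None -> synthetic default tags

    def validate(self) -> None:
        if self.min_rte_length < 0:
            raise ValueError("min_rte_length must be >= 0")
        if self.rpkm_min < 0:
            raise ValueError("rpkm_min must be >= 0")
        if not 0 <= self.cov_min <= 1:
            raise ValueError("cov_min must lie in [0, 1]")
        if not 0 < self.dedup_identity <= 1:
            raise ValueError("dedup_identity must lie in (0, 1]")
        if self.min_orf_nt < 3:
            raise ValueError("min_orf_nt must be >= 3")
        if self.mutation_rate <= 0:
            raise ValueError("mutation_rate must be positive")
        if self.recent_boundary_years <= 0:
            raise ValueError("recent_boundary_years must be positive")
        if self.acm_cutoff is not None and self.acm_cutoff < 1:
            raise ValueError("acm_cutoff must be >= 1")
        if self.group1_min_cultivars < 1:
            raise ValueError("group1_min_cultivars must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["required_domains"] = list(self.required_domains)
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "required_domains" in data:
            data["required_domains"] = tuple(data["required_domains"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def dump_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
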