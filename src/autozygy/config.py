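"""Pipeline configuration: every stated analysis parameter in one place.

Defaults are the parameters of the analysis this package models:
1 Mbp windows, 40% duplication-overlap cutoff, ROH rules (>= 2
consecutive windows, 2 Mbp minimum length, 500 kbp merge gap),
sex-specific recombination rates 8.9e-9 (male) and 1.4e-8 (female)
crossovers per nucleotide, 10,000 pedigree replicates and 5 Mbp length
bins.  The serialized config round-trips through YAML and its hash is
embedded in every report so outputs are traceable to their settings.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, field

import yaml


@dataclass
class PipelineConfig:
    # genome
    genome: str = "grch37"  # or "random"
    n_chrom: int = 22
    total_length: int = 2_881_033_286
    # synthetic truth
    background_het_rate: float = 1.0
    roh_het_rate: float = 0.05
    dup_fraction: float = 0.10
    planted_roh: list | None = None  # None -> module default
    # windows
    window_size: int = 1_000_000
    max_dup_overlap: float = 0.40
    # ROH calling
    het_threshold: float | None = None  # None -> 0.25 x median density
    min_windows: int = 2
    min_length: int = 2_000_000
    max_gap: int = 500_000
    # pedigree simulation
    male_rate: float = 8.9e-9
    female_rate: float = 1.4e-8
    n_reps: int = 10_000
    # likelihood
    bin_width: int = 5_000_000
    n_bins: int = 20
    pseudocount: float = 0.5
    # variants
    panel_size: int = 2
    # reproducibility
    seed: int = 0

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
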