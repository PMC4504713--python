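"""Configuration objects for the simulator and the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class SimConfig:
    """Parameters of a synthetic RAD-seq doubled-haploid experiment.

    The defaults mirror a barley-style DH design: 94 lines plus the two
    parents, seven chromosomes, 100 bp single-end reads carrying an 8 nt
    multiplex identifier (MID) barcode followed by a 92 bp restriction-site
    tag.
    """

    n_chromosomes: int = 7
    chrom_length_cM: float = 150.0
    n_sites: int = 200          # RAD loci per chromosome
    snp_fraction: float = 0.3   # fraction of loci polymorphic between parents
    n_lines: int = 94
    coverage_mean: float = 8.0  # mean reads per retained locus per individual
    error_rate: float = 0.0     # per-base substitution probability
    barcode_length: int = 8
    read_length: int = 100
    tag_length: int = 92
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tag_length + self.barcode_length != self.read_length:
            raise ValueError(
                "tag_length + barcode_length must equal read_length "
                f"({self.tag_length} + {self.barcode_length} != {self.read_length})"
            )
        if not (0.0 <= self.error_rate < 0.25):
            raise ValueError("error_rate must lie in [0, 0.25)")
        for name in ("n_chromosomes", "n_sites", "n_lines",
                     "barcode_length", "read_length", "tag_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.chrom_length_cM < 0:
            raise ValueError("chrom_length_cM must be non-negative")
        if self.coverage_mean < 0:
            raise ValueError("coverage_mean must be non-negative")
        if not (0.0 <= self.snp_fraction <= 1.0):
            raise ValueError("snp_fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class RunConfig:
    """Resolved parameters of a full pipeline run.

    Serializes losslessly to JSON; every pipeline run writes a manifest
    embedding this object plus the seed so the run can be reproduced
    byte-for-byte.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    # demultiplexing / tag clustering
    max_barcode_mismatch: int = 0
    min_presence_reads: int = 1
    max_tag_reads: int = 100            # repetitive-tag ceiling (strict >)
    # SNP calling
    max_mismatch: int = 2
    fisher_alpha: float = 0.01
    min_presence: float = 0.80          # fraction of individuals with a tag pair
    max_missing_abs: int = 20
    max_missing_rate: float = 0.07
    # linkage map
    p_cutoff: float = 1e-6
    gap_threshold_cM: float = 35.0
    detect_bad_data: bool = True
    # QTL scan
    scan_step_cM: float = 1.0
    n_perm: int = 1000
    perm_alpha: float = 0.05
    # QTL truth injected by the simulator: list of (chromosome index, cM, effect)
    qtl: list = field(default_factory=lambda: [[3, 105.5, 8.9]])
    pheno_mu: float = 71.0
    pheno_sigma: float = 9.9391         # gives a single-QTL PVE of 44.5% at a=8.9
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("sim"), dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
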