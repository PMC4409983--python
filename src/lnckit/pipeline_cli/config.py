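"""Structured pipeline configuration with provenance hashing.

Every threshold used anywhere in the pipeline is named here, with defaults
equal to the published values where one is printed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # inputs
    genome: str = ""
    reference_gtf: str = ""
    cufflinks_gtf: str = ""
    scripture_gtf: str = ""
    maf: str = ""
    tree: str = ""
    reference_species: str = "ref"
    root_age_tsv: str | None = None
    domains_tsv: str | None = None
    outdir: str = "results"
    seed: int = 0
    # discovery
    min_len: int = 200
    min_overlap: int = 1
    duplicate_min_fraction: float = 0.5
    # classification
    coding_min_peptide: int = 100
    coding_min_score: float = 10.0
    lnc_max_peptide: int = 50
    lnc_max_orf_fraction: float = 0.35
    lnc_max_score: float = -10.0
    omega: float = 0.2
    flank: int = 50
    neutral_min_columns: int = 100
    score_tracks: bool = False  # write per-codon bedGraph tracks
    # conservation
    min_cov: float = 0.10
    # structure
    window: int = 120
    step: int = 40
    structure_threshold: float = 0.5
    n_shuffles: int = 30
    structure_weights: tuple[float, float, float] = (-4.0, 1.5, 3.0)
    structure_max_z_rows: int = 4

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["structure_weights"] = list(d["structure_weights"])
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "structure_weights" in data:
            data["structure_weights"] = tuple(data["structure_weights"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def provenance(self) -> dict:
        from .. import __version__

        return {
            "config_hash": self.config_hash(),
            "seed": self.seed,
            "version": __version__,
            "config": self.to_dict(),
        }
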