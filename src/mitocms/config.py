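"""Pipeline configuration: every numeric threshold used across the analysis.

All lengths are in base pairs, identities are fractions in (0, 1], and the
defaults correspond to the screening conditions of the cotton CMS study this
pipeline reproduces: 20 bp minimum repeat length, 500 bp duplication floor,
1 kb "large repeat" floor, 50 bp exact synteny anchors at >= 98% block
identity, 300 bp minimum ORF length, 30 bp minimum mitochondrial-gene
fragment for chimera status, 99% identity for the novelty comparison against
the maintainer mitogenome, a 565 bp proximity window to functional genes,
two-fold / p < 0.05 differential-expression cutoffs, and a chloroplast-derived
filter of >= 90% identity, E <= 1e-5, >= 30 bp.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    # repeats
    min_repeat_len: int = 20
    dup_fragment_min: int = 500
    large_repeat_min: int = 1000
    repeat_min_identity: float = 0.95
    # synteny / unique regions
    synteny_anchor: int = 50
    synteny_min_identity: float = 0.98
    unique_min_len: int = 300
    unique_hit_identity: float = 0.90
    unique_hit_min_len: int = 100
    # ORF screen
    orf_min_len: int = 300
    chimera_gene_fragment_min: int = 30
    novelty_identity: float = 0.99
    homology_evalue_max: float = 1e-5
    # chloroplast-derived filter
    cp_identity: float = 0.90
    cp_min_len: int = 30
    # candidate criteria
    proximity_max: int = 565
    repeat_boundary_max: int = 100
    # expression
    de_fold: float = 2.0
    de_alpha: float = 0.05
    pseudocount: float = 0.5
    trend_zero_band: float = 0.25
    # transmembrane hydropathy scan
    tm_window: int = 19
    tm_threshold: float = 1.6
    # randomness
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_repeat_len", "dup_fragment_min", "large_repeat_min",
            "synteny_anchor", "unique_min_len", "unique_hit_min_len",
            "orf_min_len", "chimera_gene_fragment_min", "cp_min_len",
            "proximity_max", "tm_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in (
            "repeat_min_identity", "synteny_min_identity", "unique_hit_identity",
            "novelty_identity", "cp_identity",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.homology_evalue_max <= 0:
            raise ValueError("homology_evalue_max must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_dict(data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


DEFAULT_CONFIG = PipelineConfig()
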