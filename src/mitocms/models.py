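"""Core record types shared across the pipeline.

Conventions
-----------
* Algorithms work internally with 0-based half-open coordinates on the
  linearized (deposited-origin) sequence.
* Every record type below, and every file the pipeline writes, uses 1-based
  inclusive coordinates with ``start <= end``; the strand field carries
  direction, matching GFF3 and the tabular style of mitogenome papers
  (e.g. an ORF printed as 27,402–26,845 on "−" is stored as
  start=26845, end=27402, strand="-").
"""

from __future__ import annotations

from dataclasses import dataclass, field


VALID_BASES = frozenset("ACGTN")

GENE_CATEGORIES = (
    "complex I", "complex II", "complex III", "complex IV", "complex V",
    "cytochrome c", "ribosomal", "maturase", "tRNA", "rRNA", "other",
)


@dataclass
class Interval:
    """1-based inclusive genomic interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def from0(cls, start0: int, end0: int) -> "Interval":
        """From 0-based half-open [start0, end0)."""
        return cls(start0 + 1, end0)

    def to0(self) -> tuple[int, int]:
        return self.start - 1, self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def distance(self, other: "Interval") -> int:
        """Gap in bp between two intervals; 0 when they overlap or abut."""
        if self.overlaps(other):
            return 0
        if other.start > self.end:
            return other.start - self.end - 1
        return self.start - other.end - 1


@dataclass
class GeneModel:
    gene_name: str
    category: str = "other"
    strand: str = "+"
    exons: list[Interval] = field(default_factory=list)
    copy_index: int = 1
    complete_cds: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.copy_index < 1:
            raise ValueError("copy_index must be >= 1")
        ordered = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end >= b.start:
                raise ValueError(f"overlapping exons in {self.gene_name}")
        # exons stored in genomic order; reading order is reversed on "-"
        self.exons = ordered

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)

    @property
    def cds_length(self) -> int:
        return sum(iv.length for iv in self.exons)

    def extract_cds(self, sequence: str) -> str:
        """Spliced gene sequence in reading direction."""
        parts = [sequence[iv.start - 1:iv.end] for iv in self.exons]
        seq = "".join(parts)
        if self.strand == "-":
            seq = revcomp(seq)
        return seq


@dataclass
class Mitogenome:
    name: str
    sequence: str
    circular: bool = True
    features: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.name}: empty sequence")
        self.sequence = self.sequence.upper()
        for off, ch in enumerate(self.sequence):
            if ch not in VALID_BASES:
                raise ValueError(
                    f"{self.name}: non-IUPAC-core character {ch!r} at position {off + 1}"
                )
        n = len(self.sequence)
        for feat in self.features:
            sp = feat.span
            if sp.end > n:
                raise ValueError(
                    f"{self.name}: feature {feat.gene_name} exceeds genome length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class RepeatPair:
    interval_a: Interval
    interval_b: Interval
    orientation: str  # "direct" | "inverted"
    length: int
    identity: float

    def __post_init__(self) -> None:
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if (self.interval_a.start, self.interval_a.end) == (
            self.interval_b.start, self.interval_b.end,
        ):
            raise ValueError("repeat intervals coincide")


@dataclass
class RepeatAccounting:
    genome_length: int
    duplication_length: int
    backbone_length: int
    duplication_fraction: float
    n_fragments: int
    min_len: int
    max_len: int
    spectrum: dict[str, tuple[int, int]]  # bin label -> (n pairs, total bp)


@dataclass
class PredictedMolecule:
    kind: str  # "subcircle" | "isomer"
    length: int
    mediating: RepeatPair
    description: str = ""


@dataclass
class SyntenyBlock:
    interval_a: Interval
    interval_b: Interval
    strand: str
    identity: float
    label: str = ""


@dataclass
class UniqueRegion:
    interval: Interval
    label: str = ""
    neighbor_blocks: tuple[str, str] = ("", "")
    contained_orfs: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class VariantSite:
    gene: str
    cds_position: int  # 1-based nt position within the spliced CDS
    codons: dict[str, str]  # genome name -> codon
    amino_acids: dict[str, str] = field(default_factory=dict)
    effect: str = "unresolved"  # synonymous|nonsynonymous|nonsense|unresolved
    mutation_class: str = ""  # transition|transversion
    reference: str = ""  # name of the reference genome

    @property
    def codon_position(self) -> int:
        """1-based position of the variant within its codon."""
        return (self.cds_position - 1) % 3 + 1


@dataclass
class GeneRates:
    gene: str
    ka: float
    ks: float
    ratio: float | None  # None when ks == 0


@dataclass
class GeneFragment:
    gene: str
    orf_interval: Interval  # position of the fragment within the ORF (1-based)
    gene_interval: Interval  # matched region of the reference gene
    length: int
    identity: float


@dataclass
class OrfRecord:
    label: str
    interval: Interval
    strand: str
    length: int
    sequence: str = ""
    novel: bool | None = None
    chimeric: bool = False
    gene_fragments: list[GeneFragment] = field(default_factory=list)
    group: int | None = None  # 1 near-gene, 2 unique-region, 3 mosaic
    secondary_groups: list[int] = field(default_factory=list)
    tm_domains: int = 0
    nearest_gene: tuple[str, int, bool] | None = None  # (name, distance, same strand)
    in_unique_region: str | None = None
    at_repeat_boundary: bool = False
    maintainer_coverage: float | None = None
    translation_error: bool = False

    def __post_init__(self) -> None:
        if self.length != self.interval.length:
            raise ValueError(f"{self.label}: length != interval span")
        if self.length % 3 != 0:
            raise ValueError(f"{self.label}: length not a multiple of 3")


@dataclass
class ExpressionResult:
    feature: str
    log2fc_BA: float
    log2fc_FA: float
    pvalue_BA: float
    pvalue_FA: float
    de_flag_BA: bool
    de_flag_FA: bool


@dataclass
class CandidateEntry:
    label: str
    flags: dict[str, bool | None]
    score: int
    rank: int
    is_candidate: bool
    position: int  # genomic start, tie-break key


@dataclass
class CandidateReport:
    entries: list[CandidateEntry]

    def candidates(self) -> list[CandidateEntry]:
        return [e for e in self.entries if e.is_candidate]
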