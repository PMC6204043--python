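"""Six-frame ORF extraction and the chimeric-ORF / CMS candidate screen.

The screen mirrors classic plant-mitochondrial CMS analyses: extract all
ORFs of at least 300 bp (first ATG to stop codon, stop included), test each
against the maintainer mitogenome for novelty (no full-length match at 99%
identity), call an ORF *chimeric* when it contains at least 30 bp of a known
mitochondrial gene while not overlapping the genomic placement of an
annotated gene, group the ORFs (near-gene / unique-region / mosaic), count
putative transmembrane segments with a Kyte-Doolittle hydropathy scan, and
annotate repeat-boundary context.
"""

from __future__ import annotations

import edlib

from .config import DEFAULT_CONFIG, PipelineConfig
from .homology import find_local_matches, merge_spans
from .models import (
    GeneFragment, GeneModel, Interval, Mitogenome, OrfRecord, RepeatPair,
    UniqueRegion, revcomp,
)
from .variants import translate_codon

_STOPS = ("TAA", "TAG", "TGA")

# Kyte & Doolittle hydropathy scale
KD = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


def translate_orf(seq: str) -> str:
    """Peptide including a trailing '*' for the stop codon."""
    return "".join(translate_codon(seq[i:i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3))


def extract_orfs(
    genome: Mitogenome,
    min_len: int = 300,
    label_prefix: str = "orf",
    mode: str = "first_atg",
) -> list[OrfRecord]:
    """Stop-delimited ORFs on all six frames, >= min_len, labeled by position.

    ``mode`` is "first_atg" (ORF runs from the first ATG of the frame segment
    to its stop codon, both included) or "stop2stop" (whole frame segment
    including the stop). Circular genomes are scanned doubled; an ORF
    spanning the origin is reported with end > genome length. Only the
    longest ORF per stop codon is reported.
    """
    if mode not in ("first_atg", "stop2stop"):
        raise ValueError(f"unknown ORF mode {mode!r}")
    seq = genome.sequence
    L = len(seq)
    s = seq + seq if genome.circular else seq
    M = len(s)
    found: dict[tuple[int, int, str], str] = {}  # (start mod L, length, strand) -> sequence

    def scan(fs: str, strand: str) -> None:
        for frame in range(3):
            seg_start = frame
            i = frame
            while i + 3 <= len(fs):
                codon = fs[i:i + 3]
                if codon in _STOPS:
                    _segment(fs, seg_start, i + 3, strand)
                    seg_start = i + 3
                i += 3

    def _segment(fs: str, seg0: int, seg1: int, strand: str) -> None:
        # seg1 is the end of the stop codon (exclusive)
        if mode == "first_atg":
            start = None
            for j in range(seg0, seg1 - 3, 3):
                if fs[j:j + 3] == "ATG":
                    start = j
                    break
            if start is None:
                return
        else:
            start = seg0
        length = seg1 - start
        if length < min_len or length > L:
            return
        orf_seq = fs[start:seg1]
        if strand == "+":
            f0 = start
        else:
            f0 = M - seg1  # map reverse-scan coordinates to forward
        key = (f0 % L if genome.circular else f0, length, strand)
        found.setdefault(key, orf_seq)

    scan(s, "+")
    scan(revcomp(s), "-")
    records: list[OrfRecord] = []
    for (f0, length, strand), orf_seq in found.items():
        records.append(OrfRecord(
            label="", interval=Interval.from0(f0, f0 + length), strand=strand,
            length=length, sequence=orf_seq,
        ))
    records.sort(key=lambda o: (o.interval.start, o.interval.end, o.strand))
    for i, rec in enumerate(records, start=1):
        rec.label = f"{label_prefix}{i}"
    return records


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matched columns, total columns) from an edlib extended cigar."""
    matches = cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        cols += n
        if ch == "=":
            matches += n
    return matches, cols


def full_length_identity(orf_seq: str, genome: Mitogenome) -> float:
    """Best full-ORF identity (matches / alignment columns) into a genome.

    The whole ORF must align (infix alignment of the ORF within the genome,
    either strand); identity is computed over all alignment columns.
    """
    subject = genome.sequence + (genome.sequence[:len(orf_seq)] if genome.circular else "")
    best = 0.0
    for q in (orf_seq, revcomp(orf_seq)):
        res = edlib.align(q, subject, task="path", mode="HW")
        if res["editDistance"] < 0:
            continue
        matches, cols = _cigar_stats(res["cigar"])
        best = max(best, matches / cols if cols else 0.0)
    return best


def novelty(
    orf: OrfRecord,
    maintainer: Mitogenome,
    cfg: PipelineConfig = DEFAULT_CONFIG,
) -> bool:
    """True when no full-length match at the novelty identity floor exists."""
    return full_length_identity(orf.sequence, maintainer) < cfg.novelty_identity


def maintainer_coverage(
    orf: OrfRecord,
    maintainer: Mitogenome,
    cfg: PipelineConfig = DEFAULT_CONFIG,
) -> float:
    """Fraction of the ORF covered by local matches into the maintainer genome."""
    try:
        covered = find_local_matches(
            orf.sequence, maintainer.sequence,
            min_len=max(cfg.cp_min_len, 16),
            min_identity=cfg.cp_identity,
            max_evalue=cfg.homology_evalue_max,
        )
    except ValueError:
        return 0.0
    spans = merge_spans([a.query_interval.to0() for a in covered])
    return sum(iv.length for iv in spans) / orf.length


def classify_chimera(
    orf: OrfRecord,
    refs: dict[str, str],
    annotation: list[GeneModel],
    cfg: PipelineConfig = DEFAULT_CONFIG,
) -> OrfRecord:
    """Record reference-gene fragments inside the ORF and set chimera status.

    Chimeric: contains >= chimera_gene_fragment_min bp of a known
    mitochondrial gene, unless the ORF overlaps the genomic placement of an
    annotated gene (then excluded from chimera status regardless of matches).
    """
    fragments: list[GeneFragment] = []
    for gene_name, ref_seq in refs.items():
        if len(ref_seq) < 16:
            continue
        try:
            alns = find_local_matches(
                orf.sequence, ref_seq,
                min_len=max(cfg.chimera_gene_fragment_min, 16),
                min_identity=cfg.cp_identity,
                max_evalue=cfg.homology_evalue_max,
            )
        except ValueError:
            continue
        for a in alns:
            fragments.append(GeneFragment(
                gene=gene_name,
                orf_interval=a.query_interval,
                gene_interval=a.subject_interval,
                length=a.aligned_len,
                identity=a.identity,
            ))
    fragments.sort(key=lambda f: (f.orf_interval.start, f.gene))
    orf.gene_fragments = fragments
    overlaps_gene = any(orf.interval.overlaps(g.span) for g in annotation)
    orf.chimeric = bool(fragments) and not overlaps_gene
    return orf


def categorize(
    orf: OrfRecord,
    annotation: list[GeneModel],
    uniques: list[UniqueRegion],
    repeats: list[RepeatPair],
    cfg: PipelineConfig = DEFAULT_CONFIG,
) -> OrfRecord:
    """Assign the three-group category and positional context flags.

    Group 1: within proximity_max of a functional gene transcribed in the
    same direction. Group 2: contained in a unique region. Group 3: a mosaic
    of maintainer-homologous and novel sequence (both parts at least the
    chimera fragment floor). The lowest applicable group is primary; the
    rest are recorded as secondary.
    """
    # nearest functional gene (protein, rRNA or tRNA all qualify)
    nearest: tuple[str, int, bool] | None = None
    for g in annotation:
        d = orf.interval.distance(g.span)
        if nearest is None or d < nearest[1]:
            nearest = (g.gene_name, d, g.strand == orf.strand)
    orf.nearest_gene = nearest
    groups: list[int] = []
    if nearest is not None and nearest[1] <= cfg.proximity_max and nearest[2]:
        groups.append(1)
    container = next((u for u in uniques if u.interval.contains(orf.interval)), None)
    if container is not None:
        orf.in_unique_region = container.label
        groups.append(2)
    if orf.maintainer_coverage is not None:
        cov_bp = orf.maintainer_coverage * orf.length
        floor = cfg.chimera_gene_fragment_min
        if cov_bp >= floor and (orf.length - cov_bp) >= floor:
            groups.append(3)
    orf.group = groups[0] if groups else None
    orf.secondary_groups = groups[1:]
    large = [p for p in repeats if p.length >= cfg.large_repeat_min]
    edges = [x for p in large for x in (
        p.interval_a.start, p.interval_a.end, p.interval_b.start, p.interval_b.end,
    )]
    orf.at_repeat_boundary = any(
        abs(end - e) <= cfg.repeat_boundary_max
        for e in edges for end in (orf.interval.start, orf.interval.end)
    )
    return orf


def tm_segments(peptide: str, window: int = 19, threshold: float = 1.6) -> int:
    """Count hydrophobic segments by a sliding Kyte-Doolittle window.

    Window positions whose mean hydropathy reaches the threshold are merged
    when they overlap or abut; each merged stretch counts one segment per
    non-overlapping window it can hold.
    """
    scores = [KD[a] for a in peptide if a in KD]
    n = len(scores)
    if n < window:
        return 0
    hits = [
        i for i in range(n - window + 1)
        if sum(scores[i:i + window]) / window >= threshold
    ]
    if not hits:
        return 0
    spans = merge_spans([(i, i + window) for i in hits])
    return sum(max(1, iv.length // window) for iv in spans)


def tm_predict(orf: OrfRecord, cfg: PipelineConfig = DEFAULT_CONFIG) -> int:
    """TM-segment count of the ORF's translation; flags internal stops."""
    peptide = translate_orf(orf.sequence)
    if "*" in peptide[:-1]:
        orf.translation_error = True
        orf.tm_domains = 0
        return 0
    orf.tm_domains = tm_segments(peptide[:-1], cfg.tm_window, cfg.tm_threshold)
    return orf.tm_domains


def screen_orfs(
    sterile: Mitogenome,
    maintainer: Mitogenome,
    refs: dict[str, str],
    annotation: list[GeneModel],
    uniques: list[UniqueRegion],
    repeats: list[RepeatPair],
    cfg: PipelineConfig = DEFAULT_CONFIG,
    label_prefix: str = "orf",
) -> list[OrfRecord]:
    """Full ORF screen for one sterile-line genome against its maintainer."""
    records = extract_orfs(sterile, cfg.orf_min_len, label_prefix=label_prefix)
    for orf in records:
        ident = full_length_identity(orf.sequence, maintainer)
        orf.novel = ident < cfg.novelty_identity
        # a full-length near-identical match already implies full coverage
        orf.maintainer_coverage = ident if not orf.novel else \
            maintainer_coverage(orf, maintainer, cfg)
        if orf.novel:
            classify_chimera(orf, refs, annotation, cfg)
        categorize(orf, annotation, uniques, repeats, cfg)
        tm_predict(orf, cfg)
    return records
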