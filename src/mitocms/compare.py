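"""Pairwise mitogenome decomposition: synteny blocks, unique regions, SNP sites.

Synteny follows the anchor-and-chain approach: maximal exact matches of at
least the anchor length (default 50 bp) are chained collinearly per strand
with a bounded gap, and chains are merged into blocks whose overall identity
must reach the synteny floor (default 98%); blocks are labeled S1..Sn along
the first genome. A region of the focal genome is *unique* when no local
alignment of >= 90% identity and >= 100 bp connects it to any comparison
genome. SNP sites are single-base substitution columns extracted from
per-block alignments against a chosen reference genome; indel columns are
excluded.
"""

from __future__ import annotations

import logging

import edlib

from .config import DEFAULT_CONFIG, PipelineConfig
from .homology import covered_query_intervals, merge_spans
from .models import GeneModel, Interval, Mitogenome, SyntenyBlock, UniqueRegion, VariantSite, revcomp
from .repeats import _pair_scan

logger = logging.getLogger(__name__)

_CHAIN_GAP = 5000  # bp tolerated between anchors in both genomes
_ANCHOR_SEED = 16


def _block_identity(sa: str, sb: str) -> float:
    if not sa or not sb:
        return 0.0
    res = edlib.align(sa, sb, task="distance", mode="NW")
    cols = max(len(sa), len(sb))
    return 1.0 - res["editDistance"] / cols


def _chain_anchors(
    anchors: list[tuple[int, int, int, int]],
    max_indel: int = 300,
) -> list[list[tuple[int, int, int, int]]]:
    """Collinear chaining with a bounded gap in both genomes.

    Junctions implying an insertion or deletion larger than ``max_indel``
    (grossly unequal gaps) are never bridged, so blocks cannot span a
    unique-region-sized insertion.
    """
    anchors = sorted(anchors)
    chains: list[list[tuple[int, int, int, int]]] = []
    for an in anchors:
        a0, a1, b0, b1 = an
        placed = False
        for chain in chains:
            la0, la1, lb0, lb1 = chain[-1]
            gap_a = a0 - la1
            gap_b = b0 - lb1
            if (-200 <= gap_a <= _CHAIN_GAP and -200 <= gap_b <= _CHAIN_GAP
                    and abs(gap_a - gap_b) <= max_indel
                    and a0 >= la0 and b0 >= lb0):
                chain.append(an)
                placed = True
                break
        if not placed:
            chains.append([an])
    return chains


def _chain_to_blocks(
    chain: list[tuple[int, int, int, int]],
    seq_a: str,
    seq_b_oriented: str,
    min_identity: float,
) -> list[tuple[int, int, int, int, float]]:
    """Turn one anchor chain into blocks meeting the identity floor.

    Recursively splits a chain at its widest junction until the spanned
    region identity reaches the floor or a single anchor remains.
    """
    a0 = min(x[0] for x in chain)
    a1 = max(x[1] for x in chain)
    b0 = min(x[2] for x in chain)
    b1 = max(x[3] for x in chain)
    ident = _block_identity(seq_a[a0:a1], seq_b_oriented[b0:b1])
    if ident >= min_identity or len(chain) == 1:
        if ident >= min_identity:
            return [(a0, a1, b0, b1, ident)]
        return []
    gaps = [
        (chain[i + 1][0] - chain[i][1]) + (chain[i + 1][2] - chain[i][3])
        for i in range(len(chain) - 1)
    ]
    cut = max(range(len(gaps)), key=lambda i: gaps[i]) + 1
    return (
        _chain_to_blocks(chain[:cut], seq_a, seq_b_oriented, min_identity)
        + _chain_to_blocks(chain[cut:], seq_a, seq_b_oriented, min_identity)
    )


def anchor_chain(
    genome_a: Mitogenome,
    genome_b: Mitogenome,
    anchor_min: int = 50,
    min_identity: float | None = None,
    cfg: PipelineConfig = DEFAULT_CONFIG,
) -> list[SyntenyBlock]:
    """Syntenic blocks between two genomes from chained exact anchors."""
    if min_identity is None:
        min_identity = cfg.synteny_min_identity
    sa, sb = genome_a.sequence, genome_b.sequence
    nb = len(sb)
    raw: list[SyntenyBlock] = []
    for strand, oriented in (("+", sb), ("-", revcomp(sb))):
        anchors = [
            (a0, a1, b0, b1)
            for a0, a1, b0, b1 in _pair_scan(sa, oriented, _ANCHOR_SEED, 1.0, same=False)
            if a1 - a0 >= anchor_min
        ]
        for chain in _chain_anchors(anchors, max_indel=cfg.unique_min_len):
            for a0, a1, b0, b1, ident in _chain_to_blocks(chain, sa, oriented, min_identity):
                if strand == "+":
                    b_iv = Interval.from0(b0, b1)
                else:
                    b_iv = Interval.from0(nb - b1, nb - b0)
                raw.append(SyntenyBlock(
                    interval_a=Interval.from0(a0, a1),
                    interval_b=b_iv,
                    strand=strand,
                    identity=ident,
                ))
    # keep a non-overlapping tiling of genome A, preferring longer blocks;
    # small boundary overlaps (chance junction matches) are trimmed away
    raw.sort(key=lambda b: -b.interval_a.length)
    kept: list[SyntenyBlock] = []
    for blk in raw:
        a0, a1 = blk.interval_a.to0()
        b0, b1 = blk.interval_b.to0()
        for k in kept:
            k0, k1 = k.interval_a.to0()
            if k0 < a1 and a0 < k1:  # overlap
                if k0 <= a0 and a1 <= k1:
                    a0 = a1  # fully covered; drop below
                    break
                if k1 > a0 and k0 <= a0:  # trim left edge
                    cut = k1 - a0
                    a0 += cut
                    if blk.strand == "+":
                        b0 += cut
                    else:
                        b1 -= cut
                elif k0 < a1 and k1 >= a1:  # trim right edge
                    cut = a1 - k0
                    a1 -= cut
                    if blk.strand == "+":
                        b1 -= cut
                    else:
                        b0 += cut
                else:  # kept block sits strictly inside; drop candidate
                    a0 = a1
                    break
        # a syntenic block must at least reach the unique-region coverage
        # floor, otherwise short gene fragments inside unique regions (below
        # that floor by construction) would masquerade as blocks
        if a1 - a0 < max(anchor_min, cfg.unique_hit_min_len) or b1 <= b0:
            continue
        blk.interval_a = Interval.from0(a0, a1)
        blk.interval_b = Interval.from0(b0, b1)
        kept.append(blk)
    kept.sort(key=lambda b: b.interval_a.start)
    for i, blk in enumerate(kept, start=1):
        blk.label = f"S{i}"
    return kept


def unique_regions(
    focal: Mitogenome,
    others: list[Mitogenome],
    min_len: int | None = None,
    cfg: PipelineConfig = DEFAULT_CONFIG,
) -> list[UniqueRegion]:
    """Maximal focal intervals with no qualifying alignment into any comparison genome."""
    if not others:
        raise ValueError("at least one comparison genome required")
    if min_len is None:
        min_len = cfg.unique_min_len
    covered = covered_query_intervals(
        focal.sequence,
        [o.sequence for o in others],
        min_len=cfg.unique_hit_min_len,
        min_identity=cfg.unique_hit_identity,
        max_evalue=cfg.homology_evalue_max,
    )
    n = len(focal)
    gaps: list[tuple[int, int]] = []
    prev = 0
    for iv in covered:
        s0, e0 = iv.to0()
        if s0 > prev:
            gaps.append((prev, s0))
        prev = max(prev, e0)
    if prev < n:
        gaps.append((prev, n))
    regions = [
        UniqueRegion(interval=Interval.from0(s0, e0))
        for s0, e0 in gaps
        if e0 - s0 >= min_len
    ]
    for i, reg in enumerate(regions, start=1):
        reg.label = f"U{i}"
    return regions


def annotate_unique_regions(
    regions: list[UniqueRegion],
    blocks: list[SyntenyBlock] | None = None,
    orfs=None,
) -> list[UniqueRegion]:
    """Fill flanking synteny-block labels and contained-ORF labels in place."""
    for reg in regions:
        if blocks:
            left = [b.label for b in blocks if b.interval_a.end < reg.interval.start]
            right = [b.label for b in blocks if b.interval_a.start > reg.interval.end]
            reg.neighbor_blocks = (left[-1] if left else "", right[0] if right else "")
        if orfs:
            reg.contained_orfs = [
                o.label for o in orfs if reg.interval.contains(o.interval)
            ]
    return regions


def _aligned_base_map(
    reference: Mitogenome,
    other: Mitogenome,
    cfg: PipelineConfig,
) -> list[str | None]:
    """Per-reference-position base of `other`, None where unaligned or gapped."""
    blocks = anchor_chain(reference, other, anchor_min=cfg.synteny_anchor, cfg=cfg)
    n = len(reference)
    out: list[str | None] = [None] * n
    for blk in blocks:
        a0, a1 = blk.interval_a.to0()
        b0, b1 = blk.interval_b.to0()
        sb = other.sequence[b0:b1]
        if blk.strand == "-":
            sb = revcomp(sb)
        sa = reference.sequence[a0:a1]
        res = edlib.align(sb, sa, task="path", mode="NW")  # query=other, target=reference
        ai = a0
        qi = 0
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
                continue
            ln = int(num)
            num = ""
            if ch in "=X":
                for j in range(ln):
                    out[ai + j] = sb[qi + j]
                ai += ln
                qi += ln
            elif ch == "I":  # extra bases in other; consume query only
                qi += ln
            elif ch == "D":  # gap in other against reference positions
                ai += ln
    return out


def snp_sites(
    reference: Mitogenome,
    genomes: dict[str, Mitogenome],
    gene_models: list[GeneModel] | None = None,
    cfg: PipelineConfig = DEFAULT_CONFIG,
) -> list[VariantSite]:
    """Substitution columns among the genomes, in reference coordinates.

    ``genomes`` maps name -> genome and must not include the reference (its
    name is taken from ``reference.name``). When ``gene_models`` (annotation
    of the reference) is given, sites are restricted to annotated CDS and
    carry per-genome codons; otherwise sites are reported bare with a
    single-base "codon" per genome.
    """
    maps = {name: _aligned_base_map(reference, g, cfg) for name, g in genomes.items()}
    refseq = reference.sequence
    n = len(refseq)
    variant_pos = [
        i for i in range(n)
        if any(m[i] is not None and m[i] != refseq[i] for m in maps.values())
    ]
    sites: list[VariantSite] = []
    if gene_models is None:
        for i in variant_pos:
            codons = {reference.name: refseq[i]}
            for name, m in maps.items():
                codons[name] = m[i] if m[i] is not None else "N"
            sites.append(VariantSite(
                gene="", cds_position=i + 1, codons=codons, reference=reference.name,
            ))
        return sites
    for gene in gene_models:
        positions = _cds_positions(gene)  # genomic 0-based, reading order
        index_of = {p: k for k, p in enumerate(positions)}
        gene_variants = sorted(
            {index_of[i] for i in variant_pos if i in index_of}
        )
        emitted_codons: set[int] = set()
        for k in gene_variants:
            ci = k // 3
            if ci in emitted_codons:
                continue
            emitted_codons.add(ci)
            codon_pos = positions[3 * ci:3 * ci + 3]
            if len(codon_pos) < 3:
                continue  # incomplete terminal codon
            # positions are already in reading order; minus-strand codons
            # therefore only need complementing, not reversal
            comp = str.maketrans("ACGTN", "TGCAN")
            codons: dict[str, str] = {}
            ref_codon = "".join(refseq[p] for p in codon_pos)
            if gene.strand == "-":
                ref_codon = ref_codon.translate(comp)
            codons[reference.name] = ref_codon
            for name, m in maps.items():
                bases = [m[p] for p in codon_pos]
                if any(b is None for b in bases):
                    codon = "NNN"
                else:
                    codon = "".join(bases)  # type: ignore[arg-type]
                    if gene.strand == "-":
                        codon = codon.translate(comp)
                codons[name] = codon
            sites.append(VariantSite(
                gene=gene.gene_name,
                cds_position=3 * ci + 1 + _first_diff(codons, reference.name),
                codons=codons,
                reference=reference.name,
            ))
    return sites


def _first_diff(codons: dict[str, str], ref_name: str) -> int:
    ref = codons[ref_name]
    for i in range(3):
        for name, c in codons.items():
            if name != ref_name and len(c) == 3 and c[i] != "N" and c[i] != ref[i]:
                return i
    return 0


def _cds_positions(gene: GeneModel) -> list[int]:
    """0-based genomic positions of the spliced CDS, in reading order.

    For a minus-strand gene the genomic positions run right-to-left; the
    base at each position must then be complemented to read the codon.
    """
    pos: list[int] = []
    for iv in gene.exons:
        s0, e0 = iv.to0()
        pos.extend(range(s0, e0))
    if gene.strand == "-":
        pos.reverse()
    return pos
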