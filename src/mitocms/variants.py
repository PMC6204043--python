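"""Codon-level variant classification, NG86 Ka/Ks, and C-to-U editing candidates.

Plant mitochondria translate with the standard genetic code, so codons are
translated with it throughout. Ka/Ks follows Nei & Gojobori (1986):
synonymous/nonsynonymous site counts per codon, difference counting averaged
over all minimal mutation paths that avoid stop codons, and Jukes-Cantor
multiple-hit correction d = -3/4 ln(1 - 4/3 p).

C-to-U RNA editing in plant organelles can create canonical start and stop
codons missing from the genomic sequence; the candidates reported here are
the two genomically predictable cases: an annotated ACG first codon (edited
to AUG) and an annotated terminal codon one C-to-U event away from a
canonical stop (CGA->UGA, CAA->UAA, CAG->UAG).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

from .models import GeneModel, GeneRates, Mitogenome, VariantSite

_STOPS = frozenset(standard_dna_table.stop_codons)
_BASES = "ACGT"
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def translate_codon(codon: str) -> str:
    """Single-letter residue, '*' for stop; requires 3 unambiguous bases."""
    if codon in _STOPS:
        return "*"
    return standard_dna_table.forward_table[codon]


def _valid(codon: str) -> bool:
    return len(codon) == 3 and all(b in _BASES for b in codon)


def mutation_class(ref_base: str, alt_base: str) -> str:
    both_pur = ref_base in _PURINES and alt_base in _PURINES
    both_pyr = ref_base in _PYRIMIDINES and alt_base in _PYRIMIDINES
    return "transition" if (both_pur or both_pyr) else "transversion"


def classify_site(site: VariantSite) -> VariantSite:
    """Fill amino acids, effect and transition/transversion class in place.

    Effect is nonsynonymous iff at least two distinct residues occur among
    the genomes, nonsense when a variant introduces (or removes) a stop, and
    unresolved when any codon carries an ambiguous base.
    """
    if any(not _valid(c) for c in site.codons.values()):
        site.effect = "unresolved"
        return site
    site.amino_acids = {g: translate_codon(c) for g, c in site.codons.items()}
    residues = set(site.amino_acids.values())
    if len(residues) >= 2 and "*" in residues:
        site.effect = "nonsense"
    elif len(residues) >= 2:
        site.effect = "nonsynonymous"
    else:
        site.effect = "synonymous"
    ref_name = site.reference if site.reference in site.codons else next(iter(site.codons))
    ref_codon = site.codons[ref_name]
    classes: list[str] = []
    for name in sorted(site.codons):
        if name == ref_name:
            continue
        codon = site.codons[name]
        for i in range(3):
            if codon[i] != ref_codon[i]:
                classes.append(mutation_class(ref_codon[i], codon[i]))
    if classes:
        # single class when unambiguous; majority (ties -> transversion,
        # the commoner event in these mitogenomes) otherwise
        if len(set(classes)) == 1:
            site.mutation_class = classes[0]
        else:
            ts = classes.count("transition")
            site.mutation_class = "transition" if ts > len(classes) - ts else "transversion"
    return site


def _site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon, NG86.

    Each position contributes the fraction of its three single-base changes
    that are synonymous; changes to stop codons count as nonsynonymous.
    """
    aa = translate_codon(codon)
    syn = 0.0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if alt not in _STOPS and translate_codon(alt) == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


def _diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, NG86.

    Averaged over all orderings of the differing positions; orderings that
    pass through a stop codon are excluded (all orderings are used if every
    path is blocked).
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if nxt in _STOPS:
                blocked = True
                break
            if translate_codon(cur) == translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:  # every path hits a stop; fall back to ignoring the block
        for order in permutations(diffs):
            cur = c1
            sd = nd = 0.0
            for i in order:
                nxt = cur[:i] + c2[i] + cur[i + 1:]
                if cur in _STOPS or nxt in _STOPS or translate_codon(cur) != translate_codon(nxt):
                    nd += 1
                else:
                    sd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p <= 0:
        return 0.0
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86_kaks(cds_a: str, cds_b: str, gene: str = "") -> GeneRates:
    """Nei-Gojobori (1986) Ka, Ks and their ratio for an aligned codon pair.

    Both sequences must be equal-length, a multiple of 3, and free of
    internal stops. The ratio is None when Ks = 0.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDS lengths differ")
    if len(cds_a) % 3:
        raise ValueError("CDS length not a multiple of 3")
    n_codons = len(cds_a) // 3
    S = N = Sd = Nd = 0.0
    for k in range(n_codons):
        c1 = cds_a[3 * k:3 * k + 3]
        c2 = cds_b[3 * k:3 * k + 3]
        if not (_valid(c1) and _valid(c2)):
            continue
        if (c1 in _STOPS or c2 in _STOPS):
            if k == n_codons - 1:
                continue  # terminal stop codon is not a coding site
            raise ValueError(f"internal stop codon at codon {k + 1}")
        s1, n1 = _site_counts(c1)
        s2, n2 = _site_counts(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = _diff_counts(c1, c2)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    ratio = (ka / ks) if ks > 0 and math.isfinite(ks) else None
    return GeneRates(gene=gene, ka=ka, ks=ks, ratio=ratio)


@dataclass
class EditingCandidate:
    gene: str
    kind: str  # "start" | "stop"
    cds_position: int  # 1-based position of the edited C within the CDS
    genomic_position: int  # 1-based position on the genome forward strand
    codon_before: str
    codon_after: str


# terminal codons one C->U event (at codon position 1) away from a stop
_STOP_CREATING = {"CGA": "TGA", "CAA": "TAA", "CAG": "TAG"}


def editing_candidates(genome: Mitogenome, gene: GeneModel) -> list[EditingCandidate]:
    """Genomic C positions where a C-to-U edit creates a start or stop codon."""
    from .compare import _cds_positions

    cds = gene.extract_cds(genome.sequence)
    positions = _cds_positions(gene)
    out: list[EditingCandidate] = []
    if cds[:3] == "ACG":
        out.append(EditingCandidate(
            gene=gene.gene_name, kind="start", cds_position=2,
            genomic_position=positions[1] + 1,
            codon_before="ACG", codon_after="ATG",
        ))
    last = cds[-3:]
    if last in _STOP_CREATING:
        cds_pos = len(cds) - 2  # first base of the terminal codon
        out.append(EditingCandidate(
            gene=gene.gene_name, kind="stop", cds_position=cds_pos,
            genomic_position=positions[cds_pos - 1] + 1,
            codon_before=last, codon_after=_STOP_CREATING[last],
        ))
    return out


def classify_all(sites: list[VariantSite]) -> list[VariantSite]:
    return [classify_site(s) for s in sites]
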