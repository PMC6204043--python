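"""Synteny decomposition, unique-region calls and SNP column extraction."""

import numpy as np
import pytest

from conftest import rand_seq, random_orf
from mitocms.compare import (
    anchor_chain, annotate_unique_regions, snp_sites, unique_regions,
)
from mitocms.models import GeneModel, Interval, Mitogenome, revcomp
from mitocms.variants import classify_all


def test_self_comparison_single_full_block():
    rng = np.random.default_rng(20)
    g = Mitogenome("A", rand_seq(rng, 15000), circular=False)
    blocks = anchor_chain(g, g)
    assert len(blocks) == 1
    b = blocks[0]
    assert b.label == "S1"
    assert (b.interval_a.start, b.interval_a.end) == (1, 15000)
    assert b.strand == "+"
    assert b.identity == 1.0


def test_deletion_splits_blocks_at_exact_boundaries():
    rng = np.random.default_rng(21)
    A = rand_seq(rng, 20000)
    B = A[:8000] + A[10000:]
    blocks = anchor_chain(Mitogenome("A", A, circular=False),
                          Mitogenome("B", B, circular=False))
    assert len(blocks) == 2
    s1, s2 = blocks
    assert s1.interval_a.end <= 8001  # boundary within a chance-match base
    assert s2.interval_a.start >= 10000
    assert s2.interval_b.start == s2.interval_a.start - 2000


def test_inversion_produces_minus_strand_middle_block():
    rng = np.random.default_rng(22)
    A = rand_seq(rng, 20000)
    C = A[:8000] + revcomp(A[8000:13000]) + A[13000:]
    blocks = anchor_chain(Mitogenome("A", A, circular=False),
                          Mitogenome("C", C, circular=False))
    assert [b.strand for b in blocks] == ["+", "-", "+"]
    assert blocks[1].interval_a.start >= 8000
    assert blocks[1].interval_a.end <= 13001


def test_identical_genomes_have_no_unique_regions(cfg):
    rng = np.random.default_rng(23)
    g = Mitogenome("A", rand_seq(rng, 10000), circular=False)
    assert unique_regions(g, [g], cfg=cfg) == []


def test_planted_insertion_recovered_exactly(sim, cfg):
    regs = unique_regions(sim.sterile, [sim.maintainer], cfg=cfg)
    got = {(r.interval.start, r.interval.end) for r in regs}
    want = {(t.interval.start, t.interval.end) for t in sim.truth.uniques}
    assert got == want


def test_unique_region_annotation(sim, cfg):
    blocks = anchor_chain(sim.sterile, sim.maintainer, cfg.synteny_anchor, cfg=cfg)
    regs = unique_regions(sim.sterile, [sim.maintainer], cfg=cfg)
    annotate_unique_regions(regs, blocks)
    for r in regs:
        left, right = r.neighbor_blocks
        assert left or right


def test_blocks_and_uniques_do_not_overlap(sim, cfg):
    blocks = anchor_chain(sim.sterile, sim.maintainer, cfg.synteny_anchor, cfg=cfg)
    regs = unique_regions(sim.sterile, [sim.maintainer], cfg=cfg)
    spans = sorted(
        [b.interval_a.to0() for b in blocks] + [r.interval.to0() for r in regs]
    )
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2 + 60  # at most a chance-match sliver of overlap


def _genome_with_gene(rng, strand="+"):
    gene_seq = random_orf(rng, 60)  # 186 bp CDS
    placed = gene_seq if strand == "+" else revcomp(gene_seq)
    A = rand_seq(rng, 4000) + placed + rand_seq(rng, 4000)
    gm = GeneModel("g1", strand=strand, exons=[Interval(4001, 4000 + len(gene_seq))],
                   complete_cds=True)
    return A, gm, gene_seq


@pytest.mark.parametrize("strand", ["+", "-"])
def test_planted_snp_recovered_with_codons(strand, cfg):
    rng = np.random.default_rng(24)
    A, gm, gene_seq = _genome_with_gene(rng, strand)
    # substitute the third base of codon 11 (cds positions 31-33)
    cds_idx = 32  # 0-based
    gpos = 4000 + cds_idx if strand == "+" else 4000 + len(gene_seq) - 1 - cds_idx
    alt = list(A)
    old = alt[gpos]
    alt[gpos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[old]
    ref_g = Mitogenome("ref", A, circular=False, features=[gm])
    alt_g = Mitogenome("alt", "".join(alt), circular=False)
    sites = snp_sites(ref_g, {"alt": alt_g}, [gm], cfg)
    assert len(sites) == 1
    site = sites[0]
    assert site.gene == "g1"
    assert site.cds_position == 33
    assert site.codons["ref"] == gene_seq[30:33]
    assert len(site.codons) == 2


def test_identical_cds_yield_no_sites(cfg):
    rng = np.random.default_rng(25)
    A, gm, _ = _genome_with_gene(rng)
    g = Mitogenome("ref", A, circular=False, features=[gm])
    assert snp_sites(g, {"other": Mitogenome("other", A, circular=False)}, [gm], cfg) == []


def test_indel_columns_are_excluded(cfg):
    rng = np.random.default_rng(26)
    A, gm, _ = _genome_with_gene(rng)
    # 3 bp deletion inside the CDS of the comparison genome
    B = A[:4030] + A[4033:]
    ref_g = Mitogenome("ref", A, circular=False, features=[gm])
    alt_g = Mitogenome("alt", B, circular=False)
    sites = snp_sites(ref_g, {"alt": alt_g}, [gm], cfg)
    for s in classify_all(sites):
        # any site touching the deleted codon must be unresolved, never a SNP call
        assert s.effect in ("unresolved",) or "N" not in "".join(s.codons.values())
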