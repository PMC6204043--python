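"""ORF extraction vs a regex oracle; novelty, chimera, grouping, TM scan."""

import re

import numpy as np
import pytest

from conftest import rand_seq, random_orf
from mitocms.config import PipelineConfig
from mitocms.models import GeneModel, Interval, Mitogenome, OrfRecord, revcomp
from mitocms.orfs import (
    classify_chimera, extract_orfs, full_length_identity, maintainer_coverage,
    novelty, tm_predict, tm_segments, translate_orf,
)
from mitocms.refgenes import reference_dict

_ORF_RE = re.compile(r"(?=(ATG(?:(?!TAA|TAG|TGA)[ACGT]{3})*(?:TAA|TAG|TGA)))")


def regex_orf_oracle(seq: str, min_len: int):
    """Six-frame ORFs by regex, first-ATG-per-stop, as (start, end, strand)."""
    out = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        per_stop: dict[int, tuple[int, int]] = {}
        for m in _ORF_RE.finditer(s):
            a = m.start(1)
            b = a + len(m.group(1))
            if b - a < min_len:
                continue
            if b not in per_stop or per_stop[b][0] > a:
                per_stop[b] = (a, b)
        for a, b in per_stop.values():
            if strand == "+":
                out.add((a + 1, b, strand))
            else:
                out.add((n - b + 1, n - a, strand))
    return out


@pytest.mark.parametrize("seed", range(8))
def test_extraction_equals_regex_oracle(seed):
    rng = np.random.default_rng(600 + seed)
    seq = rand_seq(rng, 2500)
    g = Mitogenome("t", seq, circular=False)
    got = {(o.interval.start, o.interval.end, o.strand)
           for o in extract_orfs(g, 150)}
    assert got == regex_orf_oracle(seq, 150)


def test_no_atg_means_no_orfs():
    g = Mitogenome("t", "TTTCCCTAATTTCCC" * 40, circular=False)
    assert extract_orfs(g, 30) == []


def test_constructed_orf_coordinates():
    rng = np.random.default_rng(40)
    o = random_orf(rng, 132)  # 402 bp
    g = Mitogenome("t", rand_seq(rng, 500) + "TAA" + o + rand_seq(rng, 400),
                   circular=False)
    orfs = [x for x in extract_orfs(g, 300) if x.strand == "+"]
    assert len(orfs) == 1
    assert orfs[0].length == 402
    assert (orfs[0].interval.start, orfs[0].interval.end) == (504, 905)


def test_minus_strand_paper_style_span():
    """A 558 bp minus-strand ORF is reported with start < end and strand '-'."""
    rng = np.random.default_rng(41)
    o = random_orf(rng, 184)  # 558 bp
    g = Mitogenome("t", rand_seq(rng, 400) + revcomp("TAA" + o) + rand_seq(rng, 300),
                   circular=False)
    orfs = [x for x in extract_orfs(g, 300) if x.strand == "-" and x.length == 558]
    assert len(orfs) == 1
    iv = orfs[0].interval
    assert iv.end - iv.start + 1 == 558
    assert iv.start < iv.end


def test_every_orf_translates_with_single_terminal_stop(sim):
    for o in extract_orfs(sim.sterile, 300):
        pep = translate_orf(o.sequence)
        assert pep.count("*") == 1
        assert pep.endswith("*")


def test_circular_orf_spans_origin():
    rng = np.random.default_rng(42)
    o = random_orf(rng, 140)
    half = len(o) // 2
    seq = o[half:] + rand_seq(rng, 2000) + "TAA" + o[:half]
    g = Mitogenome("t", seq, circular=True)
    wrapped = [x for x in extract_orfs(g, 300)
               if x.length == len(o) and x.interval.end > len(g)]
    assert len(wrapped) == 1


def test_novelty_copied_vs_planted(sim, cfg):
    orfs = extract_orfs(sim.sterile, cfg.orf_min_len)
    planted = {(t.interval.start, t.interval.end) for t in sim.truth.orfs}
    for o in orfs:
        key = (o.interval.start, o.interval.end)
        if key in planted:
            assert novelty(o, sim.maintainer, cfg)


def test_novelty_identity_boundary(cfg):
    rng = np.random.default_rng(43)
    o = random_orf(rng, 99)  # 300 bp: 3 substitutions sit exactly at 99%
    maint = Mitogenome("m", rand_seq(rng, 3000) + o + rand_seq(rng, 2000),
                       circular=False)
    mut = list(o)
    for i in (40, 140, 240):
        mut[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mut[i]]
    rec = OrfRecord(label="x", interval=Interval(1, 300), strand="+", length=300,
                    sequence="".join(mut))
    # 3 edits over 300 bp: identity lands at the 99% floor (the optimal
    # alignment path may trade substitutions for gap columns, nudging the
    # ratio a hair above 297/300)
    assert 0.99 <= full_length_identity(rec.sequence, maint) < 0.9925
    assert not novelty(rec, maint, cfg)


def _orf_with_fragment(rng, gene_seq, frag_len, total_codons=160):
    """ORF starting with the gene's own first frag_len bases.

    The filler is forced to mismatch the gene continuation over the next
    16 bases so the fragment's maximal alignment ends exactly at frag_len.
    """
    frag = gene_seq[:frag_len]
    filler_codons = total_codons - (frag_len + 2) // 3
    body = list("".join(rng.choice(
        [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
         if a + b + c not in ("TAA", "TAG", "TGA")], size=filler_codons)))
    for i in range(16):
        if frag_len + i < len(gene_seq) and body[i] == gene_seq[frag_len + i]:
            body[i] = next(b for b in "CAGT" if b != gene_seq[frag_len + i])
    return frag + "".join(body) + "TAA"


def test_chimera_fragment_threshold(cfg):
    rng = np.random.default_rng(44)
    refs = reference_dict()
    seq45 = _orf_with_fragment(rng, refs["rps3"], 45)
    rec = OrfRecord(label="a", interval=Interval(10_000, 10_000 + len(seq45) - 1),
                    strand="+", length=len(seq45), sequence=seq45)
    rec = classify_chimera(rec, {"rps3": refs["rps3"]}, [], cfg)
    assert rec.chimeric
    [frag] = [f for f in rec.gene_fragments if f.gene == "rps3"]
    assert (frag.orf_interval.start, frag.orf_interval.end) == (1, 45)
    assert (frag.gene_interval.start, frag.gene_interval.end) == (1, 45)
    # 27 bp of gene sequence stays below the 30 bp chimera floor
    seq27 = _orf_with_fragment(rng, refs["rps3"], 27)
    rec2 = OrfRecord(label="b", interval=Interval(20_000, 20_000 + len(seq27) - 1),
                     strand="+", length=len(seq27), sequence=seq27)
    rec2 = classify_chimera(rec2, {"rps3": refs["rps3"]}, [], cfg)
    assert not rec2.chimeric


def test_chimera_excluded_when_overlapping_annotated_gene(cfg):
    rng = np.random.default_rng(45)
    refs = reference_dict()
    seq = _orf_with_fragment(rng, refs["atp6"], 60)
    gene = GeneModel("atp6", strand="+", exons=[Interval(9_500, 11_000)])
    rec = OrfRecord(label="c", interval=Interval(10_000, 10_000 + len(seq) - 1),
                    strand="+", length=len(seq), sequence=seq)
    rec = classify_chimera(rec, {"atp6": refs["atp6"]}, [gene], cfg)
    assert rec.gene_fragments  # the match is still recorded
    assert not rec.chimeric


def test_tm_extremes_and_oracle():
    assert tm_segments("L" * 30) == 1
    assert tm_segments("D" * 30) == 0
    assert tm_segments("L" * 60) == 3
    # oracle: numpy rolling-mean window scan with the same merge rule
    from mitocms.orfs import KD

    rng = np.random.default_rng(46)
    aas = list(KD)
    for _ in range(50):
        pep = "".join(rng.choice(aas, size=int(rng.integers(25, 120))))
        scores = np.array([KD[a] for a in pep])
        w = 19
        means = np.convolve(scores, np.ones(w) / w, mode="valid")
        hits = np.flatnonzero(means >= 1.6)
        if hits.size == 0:
            expected = 0
        else:
            expected = 0
            run_start = prev = hits[0]
            for h in list(hits[1:]) + [hits[-1] + w + 5]:
                if h <= prev + w:  # overlapping or abutting windows merge
                    prev = h
                    continue
                expected += max(1, (prev + w - run_start) // w)
                run_start = prev = h
            expected += 0 if hits.size == 0 else 0
        assert tm_segments(pep) == expected


def test_tm_predict_flags_internal_stop(cfg):
    seq = "ATG" + "TAA" + "CTG" * 97 + "TAA"  # internal stop after codon 1
    rec = OrfRecord(label="z", interval=Interval(1, len(seq)), strand="+",
                    length=len(seq), sequence=seq)
    assert tm_predict(rec, cfg) == 0
    assert rec.translation_error


def test_group_assignment_invariant_under_rotation(small_sim, cfg):
    """Rotating the circular genome must not change planted-ORF group calls."""
    from mitocms.compare import unique_regions
    from mitocms.orfs import categorize
    from mitocms.repeats import find_repeats

    base = small_sim.sterile
    truth = small_sim.truth

    def group_of_planted(genome, shift):
        uniq = unique_regions(genome, [small_sim.maintainer], cfg=cfg)
        reps = find_repeats(genome, cfg.min_repeat_len, 1.0)
        groups = {}
        for o in extract_orfs(genome, cfg.orf_min_len):
            o.maintainer_coverage = 0.0
            categorize(o, genome.features, uniq, reps, cfg)
            for t in truth.orfs:
                s0 = (t.interval.start - 1 + shift) % len(base) + 1
                if o.interval.start == s0:
                    groups[t.feature] = o.group
        return groups

    k = 5000
    rotated_seq = base.sequence[k:] + base.sequence[:k]
    L = len(base)
    rot_features = []
    for f in base.features:
        s0 = f.span.start - 1
        ns = (s0 - k) % L
        if ns + f.span.length <= L:  # keep genes that do not wrap after rotation
            rot_features.append(GeneModel(
                gene_name=f.gene_name, category=f.category, strand=f.strand,
                exons=[Interval(ns + 1, ns + f.span.length)],
                complete_cds=f.complete_cds,
            ))
    rotated = Mitogenome("rot", rotated_seq, circular=True, features=rot_features)
    g1 = group_of_planted(base, 0)
    g2 = group_of_planted(rotated, -k)
    common = set(g1) & set(g2)
    assert common
    for key in common:
        assert g1[key] == g2[key]


def test_maintainer_coverage_full_for_shared_orf(sim, cfg):
    orfs = extract_orfs(sim.maintainer, cfg.orf_min_len)
    assert orfs, "maintainer genome should contain ORFs (its genes)"
    o = max(orfs, key=lambda x: x.length)
    cov = maintainer_coverage(o, sim.maintainer, cfg)
    assert cov == pytest.approx(1.0, abs=0.02)
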