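"""Codon effect classification, NG86 Ka/Ks, and editing-site candidates."""

import warnings

import numpy as np
import pytest

from conftest import SENSE, random_orf
from mitocms.models import GeneModel, Interval, Mitogenome, VariantSite, revcomp
from mitocms.variants import (
    classify_site, editing_candidates, mutation_class, ng86_kaks,
)

warnings.filterwarnings("ignore", message="Bio.codonalign")


@pytest.mark.parametrize("codons,expect_effect,expect_aas", [
    # arginine/serine split seen at an atp8 variant site
    ({"A": "AGA", "S": "AGA", "E": "AGA", "B": "AGC"}, "nonsynonymous",
     {"A": "R", "B": "S"}),
    # phenylalanine third-position wobble seen at an atp4 site
    ({"A": "TTT", "B": "TTC"}, "synonymous", {"A": "F", "B": "F"}),
    ({"A": "CAA", "B": "TAA"}, "nonsense", {"A": "Q", "B": "*"}),
])
def test_codon_effect_classification(codons, expect_effect, expect_aas):
    site = classify_site(VariantSite(
        gene="g", cds_position=1, codons=dict(codons), reference="B"))
    assert site.effect == expect_effect
    for genome, aa in expect_aas.items():
        assert site.amino_acids[genome] == aa


def test_ambiguous_codon_is_unresolved():
    site = classify_site(VariantSite(
        gene="g", cds_position=1, codons={"A": "ANA", "B": "AGA"}, reference="B"))
    assert site.effect == "unresolved"


@pytest.mark.parametrize("ref,alt,expected", [
    ("A", "G", "transition"), ("C", "T", "transition"),
    ("A", "C", "transversion"), ("G", "T", "transversion"),
])
def test_transition_transversion(ref, alt, expected):
    assert mutation_class(ref, alt) == expected


def test_classification_invariant_under_genome_relabeling():
    codons = {"w": "GGA", "x": "GGC", "y": "GAA", "z": "GGA"}
    base = classify_site(VariantSite("g", 1, dict(codons), reference="w"))
    for order in (["z", "y", "x", "w"], ["x", "w", "z", "y"]):
        shuffled = {k: codons[k] for k in order}
        site = classify_site(VariantSite("g", 1, shuffled, reference="w"))
        assert site.effect == base.effect


def test_ng86_identical_and_single_change():
    cds = random_orf(np.random.default_rng(30), 100)[:-3]  # strip stop
    r = ng86_kaks(cds, cds)
    assert (r.ka, r.ks) == (0.0, 0.0)
    assert r.ratio is None
    # GGA -> GGT: glycine either way, one synonymous difference
    a = "GGA" * 100
    b = "GGT" + "GGA" * 99
    r = ng86_kaks(a, b)
    assert r.ka == 0.0
    assert r.ks > 0.0


def test_ng86_internal_stop_rejected():
    with pytest.raises(ValueError):
        ng86_kaks("ATGTAAGGG", "ATGTAAGGG")
    with pytest.raises(ValueError):
        ng86_kaks("ATGGGA", "ATG")


@pytest.mark.parametrize("seed", range(5))
def test_ng86_matches_independent_oracle(seed):
    """Cross-check against the Nei-Gojobori implementation in Biopython."""
    from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    rng = np.random.default_rng(500 + seed)
    stops = ("TAA", "TAG", "TGA")
    s1 = "".join(rng.choice(SENSE, size=90))
    s2 = list(s1)
    changed = 0
    while changed < 10:
        i = int(rng.integers(len(s1)))
        b = "ACGT"[int(rng.integers(4))]
        cand = s2.copy()
        cand[i] = b
        codon = "".join(cand[3 * (i // 3):3 * (i // 3) + 3])
        if codon not in stops:
            s2 = cand
            changed += 1
    mine = ng86_kaks(s1, "".join(s2))
    dn, ds = cal_dn_ds(CodonSeq(s1), CodonSeq("".join(s2)), method="NG86")
    assert mine.ka == pytest.approx(dn, abs=1e-9)
    assert mine.ks == pytest.approx(ds, abs=1e-9)


def test_kaks_recovers_planted_selection_regime():
    """Ka/Ks > 1 vs < 1 is recovered for planted substitution regimes."""
    from mitocms.simulate import _choose_snp  # reuse the effect-aware mutator

    rng = np.random.default_rng(31)
    correct = 0
    n_rep = 200
    for rep in range(n_rep):
        positive = rep % 2 == 0
        frac_nonsyn = 0.9 if positive else 0.1
        cds = "".join(rng.choice(SENSE, size=300))
        mutated = list(cds)
        placed = 0
        while placed < 30:
            ci = int(rng.integers(300))
            codon = "".join(mutated[3 * ci:3 * ci + 3])
            pick = _choose_snp(rng, codon, bool(rng.random() < frac_nonsyn))
            if pick is None:
                continue
            off, base = pick
            mutated[3 * ci + off] = base
            placed += 1
        r = ng86_kaks(cds, "".join(mutated))
        if r.ratio is None:
            correct += positive  # no synonymous changes at all: positive regime
        elif (r.ratio > 1) == positive:
            correct += 1
    assert correct / n_rep >= 0.95


def test_editing_start_and_stop_candidates():
    rng = np.random.default_rng(32)
    body = "".join(rng.choice([c for c in SENSE if c != "ATG"], size=20))
    seq = "ACG" + body + "CGA"
    g = Mitogenome("g", seq, circular=False)
    gm = GeneModel("rps10", strand="+", exons=[Interval(1, len(seq))])
    cands = editing_candidates(g, gm)
    kinds = {c.kind for c in cands}
    assert kinds == {"start", "stop"}
    start = next(c for c in cands if c.kind == "start")
    assert start.genomic_position == 2  # the C of ACG
    assert (start.codon_before, start.codon_after) == ("ACG", "ATG")
    stop = next(c for c in cands if c.kind == "stop")
    assert stop.genomic_position == len(seq) - 2
    assert stop.codon_after == "TGA"


def test_editing_no_candidates_for_canonical_codons():
    rng = np.random.default_rng(33)
    seq = random_orf(rng, 20)
    g = Mitogenome("g", seq, circular=False)
    gm = GeneModel("cox1", strand="+", exons=[Interval(1, len(seq))])
    assert editing_candidates(g, gm) == []


def test_editing_minus_strand_positions():
    rng = np.random.default_rng(34)
    body = "".join(rng.choice([c for c in SENSE if c != "ATG"], size=10))
    cds = "ACG" + body + "CAA"
    genome_seq = "GG" + revcomp(cds) + "CC"
    g = Mitogenome("g", genome_seq, circular=False)
    gm = GeneModel("nad1", strand="-", exons=[Interval(3, 2 + len(cds))])
    cands = editing_candidates(g, gm)
    start = next(c for c in cands if c.kind == "start")
    # the edited C (2nd CDS base) sits at the 2nd-to-last base of the
    # reverse-complemented placement
    assert start.genomic_position == 2 + len(cds) - 1
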