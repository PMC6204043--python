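"""Local-alignment search against an exhaustive Smith-Waterman oracle."""

import math

import numpy as np
import pytest

from conftest import rand_seq
from mitocms.homology import (
    GAP_EXTEND, GAP_OPEN, KCONST, LAMBDA, MATCH, MISMATCH,
    evalue, find_local_matches, merge_spans,
)
from mitocms.models import Interval, revcomp


def sw_best(query: str, subject: str):
    """Affine-gap Smith-Waterman optimum: (score, q0, q1, s0, s1) 0-based half-open."""
    n, m = len(query), len(subject)
    NEG = -10 ** 9
    H = np.zeros((m + 1,), dtype=np.int64)
    E = np.full((m + 1,), NEG, dtype=np.int64)
    best = (0, 0, 0, 0, 0)
    # traceback-free: track best score and end; rerun for start via reversal
    Hprev = np.zeros((m + 1,), dtype=np.int64)
    best_score, best_i, best_j = 0, 0, 0
    F = np.full((m + 1,), NEG, dtype=np.int64)
    for i in range(1, n + 1):
        H = np.zeros((m + 1,), dtype=np.int64)
        Enew = np.maximum(E + GAP_EXTEND, Hprev + GAP_OPEN + GAP_EXTEND)
        qi = query[i - 1]
        for j in range(1, m + 1):
            diag = Hprev[j - 1] + (MATCH if qi == subject[j - 1] else MISMATCH)
            f = max(F[j] + GAP_EXTEND, Hprev[j] + GAP_OPEN + GAP_EXTEND)
            F[j] = f
            e = max(H[j - 1] + GAP_OPEN + GAP_EXTEND, Enew[j])
            Enew[j] = e
            h = max(0, diag, e, f)
            H[j] = h
            if h > best_score:
                best_score, best_i, best_j = h, i, j
        E = Enew
        Hprev = H
    return best_score, best_i, best_j


def test_identical_sequences_single_full_alignment():
    rng = np.random.default_rng(0)
    s = rand_seq(rng, 200)
    alns = find_local_matches(s, s, 30, 0.9, 1e-5)
    assert len(alns) == 1
    a = alns[0]
    assert a.identity == 1.0
    assert a.aligned_len == 200
    assert a.strand == "+"
    assert (a.query_interval.start, a.query_interval.end) == (1, 200)


def test_single_substitution_identity():
    rng = np.random.default_rng(1)
    s = rand_seq(rng, 100)
    t = list(s)
    t[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[t[50]]
    alns = find_local_matches(s, "".join(t), 30, 0.9, 1e-5)
    assert len(alns) == 1
    assert alns[0].identity == pytest.approx(0.99)
    assert alns[0].aligned_len == 100


@pytest.mark.parametrize("seed", range(4))
def test_random_pairs_agree_with_sw_oracle(seed):
    """On unrelated sequences both the search and the SW optimum stay below threshold."""
    rng = np.random.default_rng(100 + seed)
    q, s = rand_seq(rng, 1000), rand_seq(rng, 1000)
    alns = find_local_matches(q, s, 30, 0.90, 1e-5)
    # minimum score passing E <= 1e-5 at these lengths
    min_score = math.ceil(math.log(KCONST * 1000 * 1000 / 1e-5) / LAMBDA)
    sw_fwd, _, _ = sw_best(q, s)
    sw_rev, _, _ = sw_best(q, revcomp(s))
    assert max(sw_fwd, sw_rev) < min_score
    assert alns == []


@pytest.mark.parametrize("seed", range(4))
def test_planted_homology_matches_sw_optimum(seed):
    """A planted diverged copy is found with the same extent the SW oracle reports."""
    rng = np.random.default_rng(200 + seed)
    core = rand_seq(rng, 300)
    mutated = list(core)
    for pos in rng.choice(300, size=6, replace=False):
        mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos]]
    query = rand_seq(rng, 150) + core + rand_seq(rng, 150)
    subject = rand_seq(rng, 200) + "".join(mutated) + rand_seq(rng, 100)
    alns = find_local_matches(query, subject, 30, 0.90, 1e-5)
    assert len(alns) >= 1
    top = alns[0]
    score, qi, sj = sw_best(query, subject)
    assert top.score == score
    assert top.query_interval.end == qi
    assert top.subject_interval.end == sj


@pytest.mark.parametrize("seed", range(3))
def test_strand_symmetry(seed):
    rng = np.random.default_rng(300 + seed)
    core = rand_seq(rng, 120)
    query = rand_seq(rng, 80) + core + rand_seq(rng, 60)
    subject = rand_seq(rng, 100) + core + rand_seq(rng, 90)
    fwd = find_local_matches(query, subject, 30, 0.9, 1e-5)
    rev = find_local_matches(query, revcomp(subject), 30, 0.9, 1e-5)
    assert len(fwd) == len(rev)
    n = len(subject)
    for a, b in zip(fwd, sorted(rev, key=lambda x: x.query_interval.start)):
        assert a.query_interval == b.query_interval
        assert a.strand != b.strand
        assert b.subject_interval.start == n - a.subject_interval.end + 1
        assert b.subject_interval.end == n - a.subject_interval.start + 1


def test_evalue_closed_forms():
    assert evalue(0, 10, 20) == pytest.approx(KCONST * 200)
    assert evalue(5, 10, 40) == pytest.approx(2 * evalue(5, 10, 20))
    ratio = evalue(30, 100, 100) / evalue(20, 100, 100)
    assert ratio == pytest.approx(math.exp(-10 * LAMBDA))
    with pytest.raises(ValueError):
        evalue(-1, 10, 10)


def test_min_len_below_seed_is_an_error():
    with pytest.raises(ValueError):
        find_local_matches("ACGT" * 20, "ACGT" * 20, 10, 0.9, 1e-5)


def test_merge_spans():
    merged = merge_spans([(0, 10), (5, 15), (20, 30)])
    assert [(m.start, m.end) for m in merged] == [(1, 15), (21, 30)]
    assert merge_spans([]) == []
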