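"""Repeat finder vs an all-pairs brute-force oracle; accounting arithmetic."""

import numpy as np
import pytest

from conftest import rand_seq
from mitocms.models import Mitogenome, revcomp
from mitocms.repeats import accounting, find_repeats, predict_molecules


def oracle_exact_pairs(seq: str, min_len: int):
    """All maximal exact repeat pairs by brute-force pairwise extension."""
    n = len(seq)
    rc = revcomp(seq)
    found = set()
    # direct: every ordered position pair on every diagonal
    for d in range(1, n):
        i = 0
        while i + d < n:
            if seq[i] == seq[i + d]:
                j = i
                while j + d < n and seq[j] == seq[j + d]:
                    j += 1
                if j - i >= min_len:
                    found.add(((i + 1, j), (i + d + 1, j + d), "direct"))
                i = j + 1
            else:
                i += 1
    # inverted: compare seq with rc on every diagonal, map back
    for d in range(-(n - 1), n):
        i = max(0, -d)
        while i < n and i + d < n:
            if seq[i] == rc[i + d]:
                j = i
                while j < n and j + d < n and seq[j] == rc[j + d]:
                    j += 1
                if j - i >= min_len:
                    a = (i + 1, j)
                    b = (n - (j + d) + 1, n - (i + d))
                    lo, hi = (a, b) if a <= b else (b, a)
                    if a != b:
                        found.add((lo, hi, "inverted"))
                i = j + 1
            else:
                i += 1
    return found


@pytest.mark.parametrize("seed,length", [(0, 1500), (1, 2000), (2, 1000), (3, 1800)])
def test_finder_equals_bruteforce_oracle(seed, length):
    rng = np.random.default_rng(400 + seed)
    seq = rand_seq(rng, length)
    g = Mitogenome("t", seq, circular=False)
    got = {
        ((r.interval_a.start, r.interval_a.end),
         (r.interval_b.start, r.interval_b.end), r.orientation)
        for r in find_repeats(g, 8, 1.0)
    }
    assert got == oracle_exact_pairs(seq, 8)


def test_planted_direct_and_inverted():
    rng = np.random.default_rng(9)
    # distinct junction letters on each copy stop maximal extension exactly
    # at the planted edges
    block = rand_seq(rng, 500)
    seq = (rand_seq(rng, 300) + "T" + block + "A" + rand_seq(rng, 598)
           + "C" + block + "G" + rand_seq(rng, 300))
    g = Mitogenome("d", seq, circular=False)
    [rep] = [r for r in find_repeats(g, 20, 1.0) if r.length >= 100]
    assert rep.orientation == "direct"
    assert rep.length == 500
    assert rep.interval_a.start == 302
    seq2 = (rand_seq(rng, 300) + "T" + block + "A" + rand_seq(rng, 598)
            + "C" + revcomp(block) + "C" + rand_seq(rng, 300))
    reps2 = [r for r in find_repeats(Mitogenome("i", seq2, circular=False), 20, 1.0)
             if r.length >= 100]
    assert [r.orientation for r in reps2] == ["inverted"]
    assert reps2[0].length == 500


def test_circular_origin_spanning_repeat():
    rng = np.random.default_rng(10)
    block = rand_seq(rng, 300)
    # one copy split across the origin, one internal
    seq = (block[150:] + "C" + rand_seq(rng, 1000) + "T" + block + "A"
           + rand_seq(rng, 2000) + "G" + block[:150])
    g = Mitogenome("c", seq, circular=True)
    reps = [r for r in find_repeats(g, 20, 1.0) if r.length >= 200]
    assert len(reps) == 1
    assert reps[0].length == 300
    assert reps[0].interval_b.end > len(g)  # wraps the origin


def test_accounting_copies_less_one():
    rng = np.random.default_rng(11)
    block = rand_seq(rng, 600)
    seq = ("".join(rand_seq(rng, 200)) + "T" + block + "A" + rand_seq(rng, 300)
           + "C" + block + "G" + rand_seq(rng, 250) + "A" + block + "T")
    g = Mitogenome("x", seq, circular=False)
    reps = find_repeats(g, 20, 1.0)
    acct = accounting(g, reps, 500)
    assert acct.duplication_length == 1200  # (3 - 1) x 600
    assert acct.n_fragments == 3
    assert acct.min_len == acct.max_len == 600
    assert acct.duplication_length + acct.backbone_length == len(g)


def test_accounting_no_large_repeats():
    rng = np.random.default_rng(12)
    g = Mitogenome("y", rand_seq(rng, 3000), circular=False)
    reps = find_repeats(g, 8, 1.0)
    acct = accounting(g, reps, 500)
    assert acct.duplication_length == 0
    assert acct.backbone_length == len(g)
    total = sum(bp for _, bp in acct.spectrum.values())
    assert total == sum(r.length for r in reps)


def test_partition_invariant_on_simulated_genome(sim):
    reps = find_repeats(sim.sterile, 20, 1.0)
    acct = accounting(sim.sterile, reps, 500)
    assert acct.duplication_length + acct.backbone_length == len(sim.sterile)
    assert acct.duplication_fraction == pytest.approx(
        acct.duplication_length / len(sim.sterile))


def test_predict_molecules_conservation():
    rng = np.random.default_rng(13)
    block = "".join(rng.choice(list("ACG"), size=2000))
    seq = ("T" + rand_seq(rng, 9997) + "T" + block + "T" + rand_seq(rng, 47997)
           + "T" + block + "T" + rand_seq(rng, 38000) + "T")
    g = Mitogenome("m", seq, circular=True)
    reps = [r for r in find_repeats(g, 20, 1.0) if r.length >= 1000]
    mols = predict_molecules(g, reps, 1000)
    subs = [m for m in mols if m.kind == "subcircle"]
    assert len(subs) == 2
    assert sum(m.length for m in subs) == len(g)
    # inverted repeat: a single isomer of unchanged length
    seq2 = ("T" + rand_seq(rng, 9997) + "T" + block + "T" + rand_seq(rng, 47997)
            + "T" + revcomp(block) + "T" + rand_seq(rng, 38000) + "T")
    g2 = Mitogenome("m2", seq2, circular=True)
    reps2 = [r for r in find_repeats(g2, 20, 1.0) if r.length >= 1000]
    mols2 = predict_molecules(g2, reps2, 1000)
    assert [m.kind for m in mols2] == ["isomer"]
    assert mols2[0].length == len(g2)


def test_predict_molecules_empty_without_large_repeats():
    rng = np.random.default_rng(14)
    g = Mitogenome("n", rand_seq(rng, 20000), circular=True)
    reps = find_repeats(g, 20, 1.0)
    assert predict_molecules(g, reps, 1000) == []
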