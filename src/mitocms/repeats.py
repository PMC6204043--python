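"""Maximal repeated-fragment detection and duplication accounting.

Finds maximal pairs of duplicated fragments (direct and inverted) on a
circular or linear mitogenome, computes the duplication/backbone split
("all duplicated copies less one"), the repeat size spectrum, and the
subgenomic molecules predicted from recombination across large repeats:
direct repeats > 1 kb split the master circle into two subcircles, inverted
repeats flip the internal segment and yield an isomeric master circle.

Repeat pairs are maximal with respect to the identity floor: extending
either end by one base would either hit a mismatch at the new end or push
identity below the floor. With floor 1.0 this reduces to classical maximal
exact repeat pairs. Mismatch-tolerant extension considers substitutions
only; diverged copies broken by indels are reported as separate pairs.
"""

from __future__ import annotations

import logging

from .models import Interval, Mitogenome, PredictedMolecule, RepeatAccounting, RepeatPair, revcomp

logger = logging.getLogger(__name__)

_SEED = 16
_MAX_OCC = 400  # per-k-mer cap; mitogenome-scale guard
_MISMATCH_RUN = 20  # consecutive mismatches that end a tolerant extension

SPECTRUM_BINS = (
    (">10 kb", 10001, None),
    ("1-10 kb", 1001, 10000),
    ("0.5-1 kb", 501, 1000),
    ("101-500 bp", 101, 500),
    ("41-100 bp", 41, 100),
    ("31-40 bp", 31, 40),
    ("21-30 bp", 1, 30),  # lowest figure bin; also holds the 20 bp floor
)


def _extend_pair(s1: str, s2: str, i: int, j: int, k: int, floor: float):
    """Maximal extension of an exact k-mer match s1[i:i+k] == s2[j:j+k].

    Returns (left, right): extension in bp beyond the seed on each side such
    that both ends are matches and overall identity >= floor.
    """
    # right
    matches = k
    length = k
    best_r = 0
    run = 0
    r = 0
    while True:
        a, b = i + k + r, j + k + r
        if a >= len(s1) or b >= len(s2):
            break
        if s1[a] == s2[b] and s1[a] != "N":
            matches += 1
            run = 0
            if matches / (length + r + 1) >= floor:
                best_r = r + 1
        else:
            run += 1
            if run > _MISMATCH_RUN:
                break
        r += 1
    # recompute matches over kept right extension for the left pass
    kept = s1[i:i + k + best_r]
    matches = sum(1 for a, b in zip(kept, s2[j:j + k + best_r]) if a == b and a != "N")
    length = k + best_r
    best_l = 0
    run = 0
    l = 0
    while True:
        a, b = i - l - 1, j - l - 1
        if a < 0 or b < 0:
            break
        if s1[a] == s2[b] and s1[a] != "N":
            matches += 1
            run = 0
            if matches / (length + l + 1) >= floor:
                best_l = l + 1
        else:
            run += 1
            if run > _MISMATCH_RUN:
                break
        l += 1
    return best_l, best_r


def _identity(s1: str, s2: str) -> float:
    m = sum(1 for a, b in zip(s1, s2) if a == b and a != "N")
    return m / len(s1) if s1 else 0.0


def _pair_scan(s1: str, s2: str, k: int, floor: float, same: bool):
    """Maximal matching fragment pairs between s1 and s2 as 0-based spans.

    With same=True (self comparison) only ordered pairs j > i are scanned.
    Yields (a0, a1, b0, b1) spans, deduplicated per diagonal.
    """
    index: dict[str, list[int]] = {}
    for j in range(len(s2) - k + 1):
        kmer = s2[j:j + k]
        if "N" in kmer:
            continue
        occ = index.setdefault(kmer, [])
        if len(occ) < _MAX_OCC:
            occ.append(j)
    seen_diag: dict[int, list[tuple[int, int]]] = {}
    out = []
    for i in range(len(s1) - k + 1):
        kmer = s1[i:i + k]
        if "N" in kmer:
            continue
        for j in index.get(kmer, ()):
            if same and j <= i:
                continue
            d = j - i
            covered = False
            for a0, a1 in seen_diag.get(d, ()):
                if a0 <= i and i + k <= a1:
                    covered = True
                    break
            if covered:
                continue
            left, right = _extend_pair(s1, s2, i, j, k, floor)
            a0, a1 = i - left, i + k + right
            b0, b1 = j - left, j + k + right
            seen_diag.setdefault(d, []).append((a0, a1))
            out.append((a0, a1, b0, b1))
    return out


def find_repeats(
    genome: Mitogenome,
    min_len: int = 20,
    min_identity: float = 0.95,
) -> list[RepeatPair]:
    """All maximal repeat pairs, direct and inverted, identity >= min_identity.

    Pairs are reported once, with interval_a starting before interval_b. On a
    circular genome the sequence is scanned doubled and placements are
    reduced modulo the genome length; an interval that spans the origin is
    reported with end > genome length.
    """
    if min_len < 8:
        raise ValueError("min_len below 8 is not supported")
    seq = genome.sequence
    L = len(seq)
    s = seq + seq if genome.circular else seq
    k = min(min_len, _SEED) if min_identity >= 1.0 else min(min_len, _SEED, 12)
    found: dict[tuple, RepeatPair] = {}

    def _push(a0, a1, b0, b1, orientation):
        length = a1 - a0
        if length < min_len:
            return
        if genome.circular:
            if length > L:
                return
            if orientation == "direct" and (b0 - a0) % L == 0:
                return  # trivial shift of the doubled sequence
            a0c = a0 % L
            b0c = b0 % L
        else:
            a0c, b0c = a0, b0
        a = (a0c, a0c + length)
        b = (b0c, b0c + length)
        if a == b:
            return
        if a > b:
            a, b = b, a
        key = (a, b, orientation)
        if key in found:
            return
        ident = _identity(s[a0:a1], s[b0:b1])
        found[key] = RepeatPair(
            interval_a=Interval.from0(a[0], a[1]),
            interval_b=Interval.from0(b[0], b[1]),
            orientation=orientation,
            length=length,
            identity=ident,
        )

    # direct: self comparison
    for a0, a1, b0, b1 in _pair_scan(s, s, k, min_identity, same=True):
        _push(a0, a1, b0, b1, "direct")
    # inverted: compare against the reverse complement, map back
    r = revcomp(s)
    M = len(s)
    for a0, a1, b0, b1 in _pair_scan(s, r, k, min_identity, same=False):
        # r[b0:b1] corresponds to forward span [M-b1, M-b0)
        f0, f1 = M - b1, M - b0
        if genome.circular:
            # map both copies into the first genome copy before ordering
            a0m, f0m = a0 % L, f0 % L
        else:
            a0m, f0m = a0, f0
        length = a1 - a0
        if (a0m, a0m + length) == (f0m, f0m + length):
            continue  # a perfect palindrome matching itself
        _push(a0, a1, f0, f1, "inverted")
    pairs = list(found.values())
    # identity for inverted pairs must compare one copy against the rc of the other
    fixed: list[RepeatPair] = []
    for p in pairs:
        if p.orientation == "inverted":
            sa = _slice(s, p.interval_a, L, genome.circular)
            sb = _slice(s, p.interval_b, L, genome.circular)
            p.identity = _identity(sa, revcomp(sb))
        if p.identity >= min_identity:
            fixed.append(p)
    fixed.sort(key=lambda p: (p.interval_a.start, p.interval_b.start, p.orientation))
    return fixed


def _slice(doubled: str, iv: Interval, L: int, circular: bool) -> str:
    s0, e0 = iv.to0()
    return doubled[s0:e0]


def accounting(
    genome: Mitogenome,
    repeats: list[RepeatPair],
    dup_fragment_min: int = 500,
) -> RepeatAccounting:
    """Duplication/backbone split and the repeat size spectrum.

    Fragments >= dup_fragment_min are merged where they overlap, grouped into
    families by single-linkage over the repeat pairs, and every family
    contributes the length of all copies less the longest one. The spectrum
    covers all repeat pairs with no fragment-size floor.
    """
    L = len(genome)
    big = [p for p in repeats if p.length >= dup_fragment_min]
    spans: list[tuple[int, int]] = []
    for p in big:
        spans.append(p.interval_a.to0())
        spans.append(p.interval_b.to0())
    spans = sorted(set(spans))
    # merge overlapping placements into fragments
    merged: list[list[int]] = []
    warned = False
    for s0, e0 in spans:
        if merged and s0 <= merged[-1][1]:
            if e0 > merged[-1][1] and not warned:
                logger.warning("overlapping duplicated fragments merged before counting")
                warned = True
            merged[-1][1] = max(merged[-1][1], e0)
        else:
            merged.append([s0, e0])

    def frag_id(s0: int, e0: int) -> int:
        for idx, (m0, m1) in enumerate(merged):
            if s0 >= m0 and e0 <= m1:
                return idx
        raise AssertionError("fragment not found after merge")

    parent = list(range(len(merged)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in big:
        a = frag_id(*p.interval_a.to0())
        b = frag_id(*p.interval_b.to0())
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    families: dict[int, list[int]] = {}
    for idx in range(len(merged)):
        families.setdefault(find(idx), []).append(idx)
    duplication = 0
    for members in families.values():
        lens = [merged[i][1] - merged[i][0] for i in members]
        duplication += sum(lens) - max(lens)
    duplication = min(duplication, L)
    frag_lens = [m1 - m0 for m0, m1 in merged]
    spectrum: dict[str, tuple[int, int]] = {}
    for label, lo, hi in SPECTRUM_BINS:
        in_bin = [p.length for p in repeats if p.length >= lo and (hi is None or p.length <= hi)]
        spectrum[label] = (len(in_bin), sum(in_bin))
    return RepeatAccounting(
        genome_length=L,
        duplication_length=duplication,
        backbone_length=L - duplication,
        duplication_fraction=duplication / L if L else 0.0,
        n_fragments=len(merged),
        min_len=min(frag_lens) if frag_lens else 0,
        max_len=max(frag_lens) if frag_lens else 0,
        spectrum=spectrum,
    )


def predict_molecules(
    genome: Mitogenome,
    repeats: list[RepeatPair],
    large_repeat_min: int = 1000,
) -> list[PredictedMolecule]:
    """Recombination products predicted from large repeats on a circular genome.

    Every direct repeat >= large_repeat_min predicts two subcircles whose
    lengths sum to the genome length (each retains one repeat copy); every
    inverted repeat predicts a single isomeric master circle of unchanged
    length. Nested or overlapping large repeats are handled independently.
    """
    if not genome.circular:
        raise ValueError("molecule prediction requires a circular genome")
    L = len(genome)
    large = [p for p in repeats if p.length >= large_repeat_min]
    for p in large:
        if any(q is not p and (p.interval_a.overlaps(q.interval_a) or p.interval_a.overlaps(q.interval_b))
               for q in large):
            logger.warning("nested/overlapping large repeats; predictions emitted per repeat")
            break
    out: list[PredictedMolecule] = []
    for p in large:
        if p.orientation == "direct":
            d = (p.interval_b.start - p.interval_a.start) % L
            out.append(PredictedMolecule(
                kind="subcircle", length=d, mediating=p,
                description=f"subcircle from {p.interval_a.start} to {p.interval_b.start}",
            ))
            out.append(PredictedMolecule(
                kind="subcircle", length=L - d, mediating=p,
                description=f"subcircle from {p.interval_b.start} to {p.interval_a.start}",
            ))
        else:
            out.append(PredictedMolecule(
                kind="isomer", length=L, mediating=p,
                description="isomeric master circle with internal segment inverted",
            ))
    return out
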