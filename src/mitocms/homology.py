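"""Desk-scale nucleotide local-alignment search (seed, extend, chain).

A replacement for a database BLASTN in the contexts this pipeline needs:
annotation transfer, unique-region absence checks, chloroplast-derived
filtering and chimeric-fragment mapping, where every caller additionally
imposes a length and identity floor, so the search only has to be reliable
for high-identity local homology.

Algorithm: exact k-mer seeds (default 16) are collapsed into diagonal runs,
runs are chained when close in both sequences, each chained candidate is
extended ungapped with an X-drop, realigned exactly with edlib, and the
best-scoring contiguous stretch of alignment columns is reported. Scoring is
match +1, mismatch -2, gap open -5, gap extend -2; significance uses the
Karlin-Altschul form E = K*m*n*exp(-lambda*score) with fixed approximate
ungapped constants for this scheme (lambda = 1.28, K = 0.46).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

import edlib

from .models import Interval, revcomp

SEED_SIZE = 16
MATCH = 1
MISMATCH = -2
GAP_OPEN = -5
GAP_EXTEND = -2
LAMBDA = 1.28
KCONST = 0.46
XDROP = 20
_MAX_SEED_OCC = 200  # per-k-mer occurrence cap, guards repeat-dense inputs
_RUN_JOIN = 48       # bp gap bridged when merging seeds on one diagonal
_CHAIN_JOIN = 800    # bp gap bridged when chaining runs across diagonals


@dataclass
class LocalAlignment:
    query_interval: Interval
    subject_interval: Interval
    strand: str
    matches: int
    aligned_len: int
    identity: float
    score: int
    evalue: float

    def as_tab(self) -> str:
        """BLAST outfmt-6-like row (identity in %, mismatches = non-match columns)."""
        return "\t".join(str(x) for x in (
            round(self.identity * 100, 2), self.aligned_len,
            self.aligned_len - self.matches,
            self.query_interval.start, self.query_interval.end,
            self.subject_interval.start, self.subject_interval.end,
            self.strand, self.score, f"{self.evalue:.2g}",
        ))


def evalue(score: int, m: int, n: int) -> float:
    """Expected chance alignments of at least this score between sequences of length m and n."""
    if score < 0:
        raise ValueError("score must be >= 0")
    return KCONST * m * n * math.exp(-LAMBDA * score)


def _seed_index(subject: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(subject) - k + 1):
        kmer = subject[i:i + k]
        if "N" in kmer:
            continue
        hits = index.setdefault(kmer, [])
        if len(hits) < _MAX_SEED_OCC:
            hits.append(i)
    return index


def _diagonal_runs(query: str, subject: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal-ish exact runs as (qstart, sstart, length), 0-based."""
    index = _seed_index(subject, k)
    by_diag: dict[int, list[int]] = {}
    for q in range(len(query) - k + 1):
        kmer = query[q:q + k]
        if "N" in kmer:
            continue
        for s in index.get(kmer, ()):
            by_diag.setdefault(q - s, []).append(q)
    runs: list[tuple[int, int, int]] = []
    for diag, qs in by_diag.items():
        qs.sort()
        start = prev = qs[0]
        for q in qs[1:]:
            if q - prev <= _RUN_JOIN:
                prev = q
            else:
                runs.append((start, start - diag, prev + k - start))
                start = prev = q
        runs.append((start, start - diag, prev + k - start))
    return runs


def _chain_runs(runs: list[tuple[int, int, int]]) -> list[list[tuple[int, int, int]]]:
    """Greedy single-pass chaining of diagonal runs that are close in both sequences."""
    runs = sorted(runs, key=lambda r: (r[0], r[1]))
    chains: list[list[tuple[int, int, int]]] = []
    ends: list[tuple[int, int]] = []  # (qend, send) per open chain
    for run in runs:
        q0, s0, ln = run
        placed = False
        for i in range(len(chains) - 1, -1, -1):
            qe, se = ends[i]
            if -_RUN_JOIN <= q0 - qe <= _CHAIN_JOIN and -_RUN_JOIN <= s0 - se <= _CHAIN_JOIN:
                chains[i].append(run)
                ends[i] = (max(qe, q0 + ln), max(se, s0 + ln))
                placed = True
                break
        if not placed:
            chains.append([run])
            ends.append((q0 + ln, s0 + ln))
    return chains


def _extend_ungapped(query: str, subject: str, q: int, s: int, direction: int) -> int:
    """X-drop ungapped extension; returns number of columns advanced."""
    best = cur = 0
    best_adv = adv = 0
    while True:
        qi = q + direction * adv if direction > 0 else q - adv - 1
        si = s + direction * adv if direction > 0 else s - adv - 1
        if direction > 0:
            qi, si = q + adv, s + adv
        if qi < 0 or si < 0 or qi >= len(query) or si >= len(subject):
            break
        a, b = query[qi], subject[si]
        cur += MATCH if (a == b and a != "N") else MISMATCH
        adv += 1
        if cur > best:
            best, best_adv = cur, adv
        if cur < best - XDROP:
            break
    return best_adv


def _cigar_items(cigar: str) -> list[tuple[str, int]]:
    items: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            items.append((ch, int(num)))
            num = ""
    return items


def _positive_windows(query: str, subject: str, qa: int, qb: int, sa: int, sb: int):
    """Globally align the candidate region pair; return every maximal
    positive-scoring stretch of alignment columns.

    A chained candidate can contain several homologous stretches separated
    by poorly scoring spans (e.g. either side of an insertion breakpoint);
    each is reported as its own window. Windows are
    (q0, q1, s0, s1, matches, aligned_len, score) in 0-based half-open
    coordinates.
    """
    qseq, sseq = query[qa:qb], subject[sa:sb]
    if not qseq or not sseq:
        return []
    res = edlib.align(qseq, sseq, task="path", mode="NW")
    items = _cigar_items(res["cigar"])
    # unit list: (score, dq, ds, matches, columns); gap runs kept atomic
    units: list[tuple[int, int, int, int, int]] = []
    for op, n in items:
        if op == "=":
            units.extend((MATCH, 1, 1, 1, 1) for _ in range(n))
        elif op == "X":
            units.extend((MISMATCH, 1, 1, 0, 1) for _ in range(n))
        elif op == "I":  # consumes query
            units.append((GAP_OPEN + GAP_EXTEND * n, n, 0, 0, n))
        elif op == "D":  # consumes subject
            units.append((GAP_OPEN + GAP_EXTEND * n, 0, n, 0, n))
    # prefix sums over units for O(1) window statistics
    n = len(units)
    arr = np.array(units, dtype=np.int64)
    cum = np.zeros((n + 1, 5), dtype=np.int64)
    np.cumsum(arr, axis=0, out=cum[1:])

    windows: list[tuple[int, int, int, int, int, int, int]] = []

    def best_subarray(lo: int, hi: int) -> tuple[int, int, int]:
        """Max-score unit range [i0, i1) within [lo, hi); (score, i0, i1)."""
        best_score, bi0, bi1 = 0, lo, lo
        cur, start = 0, lo
        for i in range(lo, hi):
            if cur <= 0:
                cur, start = 0, i
            cur += int(arr[i, 0])
            if cur > best_score:
                best_score, bi0, bi1 = cur, start, i + 1
        return best_score, bi0, bi1

    def rec(lo: int, hi: int) -> None:
        score, i0, i1 = best_subarray(lo, hi)
        if score <= 0 or i1 <= i0:
            return
        d = cum[i1] - cum[i0]
        windows.append((qa + int(cum[i0, 1]), qa + int(cum[i1, 1]),
                        sa + int(cum[i0, 2]), sa + int(cum[i1, 2]),
                        int(d[3]), int(d[4]), score))
        rec(lo, i0)
        rec(i1, hi)

    rec(0, n)
    return windows


def find_local_matches(
    query: str,
    subject: str,
    min_len: int,
    min_identity: float,
    max_evalue: float,
    seed_size: int = SEED_SIZE,
) -> list[LocalAlignment]:
    """All maximal high-identity local alignments on both strands.

    Alignments must satisfy aligned_len >= min_len, identity >= min_identity
    and E-value <= max_evalue; alignments wholly contained (query and subject)
    in a higher-scoring reported one are suppressed.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    if min_len < seed_size:
        raise ValueError(f"min_len ({min_len}) below seed size ({seed_size})")
    query = query.upper()
    subject = subject.upper()
    n_subj = len(subject)
    out: list[LocalAlignment] = []
    for strand, subj in (("+", subject), ("-", revcomp(subject))):
        for chain in _chain_runs(_diagonal_runs(query, subj, seed_size)):
            q0 = min(r[0] for r in chain)
            s0 = min(r[1] for r in chain)
            q1 = max(r[0] + r[2] for r in chain)
            s1 = max(r[1] + r[2] for r in chain)
            left = min(_extend_ungapped(query, subj, q0, s0, -1), q0, s0)
            right = _extend_ungapped(query, subj, q1, s1, +1)
            for win in _positive_windows(query, subj, q0 - left, q1 + right,
                                         s0 - left, s1 + right):
                wq0, wq1, ws0, ws1, matches, cols, score = win
                if cols < min_len or wq1 <= wq0 or ws1 <= ws0:
                    continue
                identity = matches / cols
                if identity < min_identity:
                    continue
                ev = evalue(score, len(query), n_subj)
                if ev > max_evalue:
                    continue
                if strand == "+":
                    s_iv = Interval.from0(ws0, ws1)
                else:
                    s_iv = Interval.from0(n_subj - ws1, n_subj - ws0)
                out.append(LocalAlignment(
                    query_interval=Interval.from0(wq0, wq1),
                    subject_interval=s_iv,
                    strand=strand,
                    matches=matches,
                    aligned_len=cols,
                    identity=identity,
                    score=score,
                    evalue=ev,
                ))
    out = _suppress_contained(out)
    out.sort(key=lambda a: (-a.score, a.query_interval.start))
    return out


def _suppress_contained(alns: list[LocalAlignment]) -> list[LocalAlignment]:
    kept: list[LocalAlignment] = []
    for a in sorted(alns, key=lambda x: (-x.score, x.query_interval.start)):
        contained = any(
            k.strand == a.strand
            and k.query_interval.contains(a.query_interval)
            and k.subject_interval.contains(a.subject_interval)
            for k in kept
        )
        if not contained:
            kept.append(a)
    return kept


def covered_query_intervals(
    query: str,
    subjects: list[str],
    min_len: int,
    min_identity: float,
    max_evalue: float,
) -> list[Interval]:
    """Merged query intervals covered by a qualifying alignment into any subject."""
    spans: list[tuple[int, int]] = []
    for subj in subjects:
        for aln in find_local_matches(query, subj, min_len, min_identity, max_evalue):
            spans.append(aln.query_interval.to0())
    return merge_spans(spans)


def merge_spans(spans: list[tuple[int, int]]) -> list[Interval]:
    """Merge 0-based half-open spans into disjoint 1-based intervals."""
    if not spans:
        return []
    spans = sorted(spans)
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [Interval.from0(s, e) for s, e in merged]
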