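"""Synthetic mitogenome trios with planted truth for every pipeline stage.

The generator emulates the structure of a CMS / maintainer mitogenome pair
derived from a common ancestor: an annotated circular ancestor carries a
sample of the reference genes; the maintainer-like genome differs from the
ancestor only by its own coding SNPs; the sterile-like genome additionally
carries planted large repeats (direct and inverted extra copies of backbone
segments), unique-region insertions of novel sequence containing chimeric
ORFs (a reference-gene fragment fused to novel coding sequence), and its own
SNPs. Per-feature count tables for the CMS (A), maintainer (B) and
fertility-restored F1 libraries are drawn Poisson around specified means
and fold changes. Every planted event is recorded in a TruthTable in final
sterile-genome coordinates, so recovery can be scored exactly.

Planting is junction-aware: inserted copies and insertions are placed so
that the bases flanking each junction mismatch their counterparts, which
makes the planted coordinates the exact maximal extents a detector should
report. Substitution noise, when requested, is frame-aware inside planted
ORFs (it never creates an in-frame stop or destroys the start codon),
emulating coding-sequence constraint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import GeneModel, Interval, Mitogenome
from .refgenes import RefGene, reference_genes, _SENSE_NO_ATG, _STOPS

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class PlantedRepeatSpec:
    length: int = 2000
    orientation: str = "direct"
    copies: int = 2


@dataclass
class PlantedUniqueSpec:
    length: int = 3000
    n_chimeric_orfs: int = 1
    gene_fragment_lengths: tuple[int, ...] = (45,)
    orf_length: int = 402
    near_gene: bool = True


@dataclass
class SimulationSpec:
    ancestor_length: int = 80_000
    n_genes: int = 20
    planted_repeats: list[PlantedRepeatSpec] = field(default_factory=lambda: [
        PlantedRepeatSpec(2000, "direct", 2),
        PlantedRepeatSpec(1200, "inverted", 2),
    ])
    planted_unique: list[PlantedUniqueSpec] = field(default_factory=lambda: [
        PlantedUniqueSpec(3000, 1, (45,), 402, True),
        PlantedUniqueSpec(2400, 1, (60,), 501, False),
    ])
    n_snps: int = 24
    frac_nonsynonymous: float = 0.75
    counts_spec: dict[str, tuple[float, float, float]] | None = None
    noise_rate: float = 0.0
    gc: float = 0.45
    seed: int = 0


@dataclass
class TruthRepeat:
    interval_a: Interval
    interval_b: Interval
    orientation: str
    length: int


@dataclass
class TruthOrfFragment:
    gene: str
    orf_interval: Interval
    gene_interval: Interval


@dataclass
class TruthOrf:
    feature: str  # count-table feature name
    interval: Interval  # in the sterile genome
    strand: str
    fragments: list[TruthOrfFragment]
    unique_label: str
    near_gene: str | None  # same-strand gene within the proximity window


@dataclass
class TruthUnique:
    label: str
    interval: Interval


@dataclass
class TruthSnp:
    genome: str  # "sterile" | "maintainer"
    gene: str
    cds_position: int
    ref_codon: str
    alt_codon: str
    effect: str  # expected: synonymous | nonsynonymous


@dataclass
class TruthTable:
    repeats: list[TruthRepeat]
    uniques: list[TruthUnique]
    orfs: list[TruthOrf]
    snps: list[TruthSnp]
    expected_de: dict[str, dict[str, bool]]  # feature -> {BA, FA}

    def match_orf(self, interval: Interval, min_jaccard: float = 0.8) -> TruthOrf | None:
        """Planted ORF matching a recovered interval, by reciprocal overlap."""
        for t in self.orfs:
            inter = (min(t.interval.end, interval.end)
                     - max(t.interval.start, interval.start) + 1)
            union = (max(t.interval.end, interval.end)
                     - min(t.interval.start, interval.start) + 1)
            if inter > 0 and inter / union >= min_jaccard:
                return t
        return None

    def to_json(self, path: str | Path) -> None:
        def enc(o):
            if isinstance(o, Interval):
                return {"start": o.start, "end": o.end}
            return o.__dict__
        Path(path).write_text(json.dumps(self, default=enc, indent=1))


@dataclass
class SimulationResult:
    ancestor: Mitogenome
    sterile: Mitogenome
    maintainer: Mitogenome
    counts: "CountTable"
    truth: TruthTable


class PlacementError(RuntimeError):
    pass


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _place(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    length: int,
    lo: int,
    hi: int,
    margin: int = 150,
    tries: int = 500,
    accept=None,
) -> int:
    """A start position in [lo, hi) whose [pos, pos+length) avoids occupied spans.

    Samples uniformly over the actually feasible gaps (so dense genomes do
    not dead-end); the separation margin is relaxed progressively.
    """
    for use_margin in (margin, margin // 2, 20):
        spans = sorted(occupied)
        gaps: list[tuple[int, int]] = []  # feasible [start, start_max) ranges
        cursor = lo
        for s, e in spans + [(hi, hi)]:
            gap_end = min(s - use_margin, hi)
            if gap_end - cursor >= length:
                gaps.append((cursor, gap_end - length + 1))
            cursor = max(cursor, e + use_margin)
        if not gaps:
            continue
        widths = np.array([b - a for a, b in gaps], dtype=float)
        for _ in range(tries):
            gi = int(rng.choice(len(gaps), p=widths / widths.sum()))
            a, b = gaps[gi]
            pos = int(rng.integers(a, b))
            if accept is not None and not accept(pos):
                continue
            occupied.append((pos, pos + length))
            return pos
    raise PlacementError(f"could not place an event of length {length}")


def _choose_snp(
    rng: np.random.Generator,
    codon: str,
    want_nonsyn: bool,
) -> tuple[int, str] | None:
    """(position in codon, new base) giving the requested effect, or None."""
    from .variants import translate_codon

    aa = translate_codon(codon)
    options = []
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if alt in _STOPS:
                continue
            if (translate_codon(alt) != aa) == want_nonsyn:
                options.append((i, b))
    if not options:
        return None
    return options[int(rng.integers(len(options)))]


def simulate(spec: SimulationSpec) -> SimulationResult:
    """Generate the ancestor / sterile / maintainer trio with planted truth."""
    from .expression import CountTable

    rng = np.random.default_rng(spec.seed)
    refs = reference_genes()
    L = spec.ancestor_length
    ancestor_seq = list(_rand_seq(rng, L, spec.gc))

    # --- gene placement on the ancestor ---
    proteins = [g for g in refs if g.is_protein]
    rnas = [g for g in refs if not g.is_protein]
    chosen: list[RefGene] = list(
        rng.choice(proteins, size=min(spec.n_genes - 2, len(proteins)), replace=False)
    )
    chosen += [g for g in rnas if g.name == "rrn26"][:1]
    chosen += [g for g in rnas if g.name == "rrn18"][:1]
    occupied: list[tuple[int, int]] = []
    features: list[GeneModel] = []
    gene_pos: dict[str, tuple[int, str]] = {}  # name -> (0-based start, strand)
    for g in chosen:
        strand = "+" if rng.random() < 0.5 else "-"
        pos = _place(rng, occupied, len(g.sequence), 1000, L - 1000)
        seq = g.sequence
        if strand == "-":
            seq = "".join(_COMP[b] for b in reversed(seq))
        ancestor_seq[pos:pos + len(seq)] = seq
        features.append(GeneModel(
            gene_name=g.name, category=g.category, strand=strand,
            exons=[Interval(pos + 1, pos + len(seq))],
            complete_cds=g.is_protein,
        ))
        gene_pos[g.name] = (pos, strand)
    features.sort(key=lambda f: f.span.start)

    # --- SNP planting (substitutions; applied before any insertion) ---
    protein_feats = [f for f in features if f.complete_cds]
    snps: list[TruthSnp] = []
    snp_edits: dict[str, list[tuple[int, str]]] = {"sterile": [], "maintainer": []}
    used_codons: set[tuple[str, int]] = set()
    snps_per_gene: dict[str, int] = {}
    from .variants import translate_codon  # noqa: F401  (used via _choose_snp)
    attempts = 0
    while len(snps) < spec.n_snps and attempts < spec.n_snps * 50:
        attempts += 1
        feat = protein_feats[int(rng.integers(len(protein_feats)))]
        n_codons = feat.cds_length // 3
        # density cap mirrors real mitogenome SNP sparsity and keeps shared
        # backbone ORFs above the novelty identity floor
        cap = max(1, feat.cds_length // 300)
        if snps_per_gene.get(feat.gene_name, 0) >= cap:
            continue
        ci = int(rng.integers(1, n_codons - 1))  # spare start and stop codons
        if (feat.gene_name, ci) in used_codons:
            continue
        pos0, strand = gene_pos[feat.gene_name]
        cds = "".join(ancestor_seq[pos0:pos0 + feat.cds_length])
        if strand == "-":
            cds = "".join(_COMP[b] for b in reversed(cds))
        codon = cds[3 * ci:3 * ci + 3]
        want_nonsyn = bool(rng.random() < spec.frac_nonsynonymous)
        pick = _choose_snp(rng, codon, want_nonsyn)
        if pick is None:
            continue
        off, base = pick
        cds_index = 3 * ci + off  # 0-based within CDS
        if strand == "+":
            gpos = pos0 + cds_index
            gbase = base
        else:
            gpos = pos0 + feat.cds_length - 1 - cds_index
            gbase = _COMP[base]
        target = "sterile" if len(snps) % 2 == 0 else "maintainer"
        alt_codon = codon[:off] + base + codon[off + 1:]
        snp_edits[target].append((gpos, gbase))
        used_codons.add((feat.gene_name, ci))
        snps_per_gene[feat.gene_name] = snps_per_gene.get(feat.gene_name, 0) + 1
        snps.append(TruthSnp(
            genome=target, gene=feat.gene_name, cds_position=cds_index + 1,
            ref_codon=codon, alt_codon=alt_codon,
            effect="nonsynonymous" if want_nonsyn else "synonymous",
        ))

    maintainer_seq = ancestor_seq.copy()
    for gpos, gbase in snp_edits["maintainer"]:
        maintainer_seq[gpos] = gbase
    sterile_base = ancestor_seq.copy()
    for gpos, gbase in snp_edits["sterile"]:
        sterile_base[gpos] = gbase

    insertions: list[tuple[int, str, str, dict]] = []  # (backbone pos, seq, kind, meta)

    def _junction_ok_direct(p: int, s0: int, s1: int) -> bool:
        return (ancestor_seq[p] != ancestor_seq[s1]
                and ancestor_seq[p - 1] != ancestor_seq[s0 - 1])

    def _junction_ok_inverted(p: int, s0: int, s1: int) -> bool:
        return (ancestor_seq[s0 - 1] != _COMP[ancestor_seq[p]]
                and ancestor_seq[s1] != _COMP[ancestor_seq[p - 1]])

    # --- unique insertions containing chimeric ORFs ---
    ref_by_name = {g.name: g for g in refs}
    protein_names = [g.name for g in refs if g.is_protein]
    truth_unique_raw = []  # (backbone pos, length, orfs=[(offset, length, fragments, feature, near)])
    for ui, uspec in enumerate(spec.planted_unique):
        orf_parts: list[tuple[int, int, list, str, str | None]] = []
        cursor = 0
        pieces: list[str] = []
        total_orf = sum(uspec.orf_length + 3 for _ in range(uspec.n_chimeric_orfs))
        slack = uspec.length - total_orf
        if slack < 40 * (uspec.n_chimeric_orfs + 1):
            raise PlacementError(f"unique insertion {ui + 1} too short for its ORFs")
        # near-gene insertions keep the first ORF close to the left junction so
        # the planted proximity stays inside the window
        lead = 40 if uspec.near_gene else slack // (uspec.n_chimeric_orfs + 1)
        gap = (slack - lead) // max(uspec.n_chimeric_orfs, 1)
        near = None
        for oi in range(uspec.n_chimeric_orfs):
            frag_lens = uspec.gene_fragment_lengths
            fl = frag_lens[oi % len(frag_lens)]
            fl = ((fl + 2) // 3) * 3  # codon-aligned fragment
            gene = protein_names[int(rng.integers(len(protein_names)))]
            gene_seq = ref_by_name[gene].sequence
            frag = gene_seq[:fl]  # starts at the gene's ATG
            n_fill = (uspec.orf_length - fl - 3) // 3
            filler_codons = list(rng.choice(_SENSE_NO_ATG, size=n_fill))
            # the first filler codons must mismatch the gene continuation at
            # every base, so the fragment's maximal alignment ends at fl
            for k in range(min(3, n_fill)):
                cont = gene_seq[fl + 3 * k:fl + 3 * k + 3]
                if len(cont) < 3:
                    break
                choices = [c for c in _SENSE_NO_ATG
                           if all(c[j] != cont[j] for j in range(3))]
                filler_codons[k] = choices[int(rng.integers(len(choices)))]
            filler = "".join(filler_codons)
            orf_seq = frag + filler + str(rng.choice(list(_STOPS)))
            pad_len = (lead if oi == 0 else gap) - 3
            filler_pad = _rand_seq(rng, max(pad_len, 10), spec.gc)
            pieces.append(filler_pad)
            cursor += len(filler_pad)
            pieces.append("TAA")  # in-frame stop: the ORF's first ATG is its start
            cursor += 3
            fragments = [TruthOrfFragment(
                gene=gene,
                orf_interval=Interval(1, fl),
                gene_interval=Interval(1, fl),
            )]
            orf_parts.append((cursor, len(orf_seq), fragments,
                              f"sim_orf_{ui + 1}_{oi + 1}", None))
            pieces.append(orf_seq)
            cursor += len(orf_seq)
        tail = uspec.length - cursor
        pieces.append(_rand_seq(rng, max(tail, 1), spec.gc))
        novel = "".join(pieces)[:uspec.length]

        if uspec.near_gene:
            plus_genes = [f for f in features if f.strand == "+"]
            if not plus_genes:
                raise PlacementError("no plus-strand gene for near-gene placement")
            first_orf_off = orf_parts[0][0]
            max_gap = max(20, 500 - first_orf_off)
            pos = None
            order = rng.permutation(len(plus_genes))
            for gi in order:
                host = plus_genes[int(gi)]
                g_end0 = host.span.end  # 0-based position just after the gene
                for gap_try in range(40, max_gap, 13):
                    p = g_end0 + gap_try
                    if p + uspec.length >= L - 1000:
                        continue
                    clear = all(
                        p + uspec.length + 20 <= s or p >= e + 20
                        for s, e in occupied
                        if not (s <= g_end0 <= e)  # the host gene's own span
                    )
                    if clear:
                        pos = p
                        occupied.append((p, p + uspec.length))
                        near = host.gene_name
                        break
                if pos is not None:
                    break
            if pos is None:
                # no plus-strand gene has room downstream: plant a small
                # companion gene (shared by all three genomes) just upstream
                # of a freely placed insertion point
                placed_names = set(gene_pos)
                companions = sorted(
                    (g for g in refs if g.name not in placed_names
                     and len(g.sequence) <= 600),
                    key=lambda g: len(g.sequence),
                )
                if not companions:
                    raise PlacementError("could not place near-gene unique insertion")
                comp_gene = companions[0]
                glen = len(comp_gene.sequence)
                gap = 80

                def room_for_companion(q: int) -> bool:
                    a = q - gap - glen
                    return a > 1000 and all(
                        a - 20 >= e or q + uspec.length + 20 <= s
                        for s, e in occupied
                    )

                pos = _place(rng, occupied, uspec.length, 1000, L - 1000,
                             accept=room_for_companion)
                gstart = pos - gap - glen
                occupied.append((gstart, gstart + glen))
                for target in (ancestor_seq, maintainer_seq, sterile_base):
                    target[gstart:gstart + glen] = comp_gene.sequence
                feat = GeneModel(
                    gene_name=comp_gene.name, category=comp_gene.category,
                    strand="+", exons=[Interval(gstart + 1, gstart + glen)],
                    complete_cds=comp_gene.is_protein,
                )
                features.append(feat)
                features.sort(key=lambda f: f.span.start)
                gene_pos[comp_gene.name] = (gstart, "+")
                near = comp_gene.name
        else:
            def far_from_genes(q: int) -> bool:
                return all(
                    q - (f.span.end) > 700 or (f.span.start - 1) - (q + uspec.length) > 700
                    for f in features
                )
            pos = _place(rng, occupied, uspec.length, 1000, L - 1000,
                         accept=far_from_genes)
        # junction guards: the first/last 6 inserted bases mismatch the
        # ancestor continuation, so alignment-based boundary recovery is exact
        novel_l = list(novel)
        for i in range(6):
            if novel_l[i] == sterile_base[pos + i]:
                alts = [b for b in "ACGT" if b != sterile_base[pos + i]]
                novel_l[i] = alts[int(rng.integers(3))]
            if novel_l[-1 - i] == sterile_base[pos - 1 - i]:
                alts = [b for b in "ACGT" if b != sterile_base[pos - 1 - i]]
                novel_l[-1 - i] = alts[int(rng.integers(3))]
        novel = "".join(novel_l)
        insertions.append((pos, novel, "unique", {"index": ui}))
        truth_unique_raw.append((pos, uspec.length, orf_parts, near))


    # --- planted repeats: extra copies of backbone segments ---
    truth_repeats_raw: list[tuple[int, list[tuple[int, bool]], int, str]] = []
    for rep in spec.planted_repeats:
        if rep.orientation not in ("direct", "inverted"):
            raise ValueError(f"bad orientation {rep.orientation!r}")
        src = _place(rng, occupied, rep.length, 1000, L - 1000)
        src_seq = "".join(sterile_base[src:src + rep.length])
        copy_positions: list[tuple[int, bool]] = []
        for _ in range(rep.copies - 1):
            ok = (_junction_ok_direct if rep.orientation == "direct"
                  else _junction_ok_inverted)
            p = _place(rng, occupied, rep.length, 1000, L - 1000,
                       accept=lambda q: ok(q, src, src + rep.length))
            ins_seq = src_seq if rep.orientation == "direct" else \
                "".join(_COMP[b] for b in reversed(src_seq))
            insertions.append((p, ins_seq, "repeat", {}))
            copy_positions.append((p, True))
        truth_repeats_raw.append((src, copy_positions, rep.length, rep.orientation))

    # --- assemble the sterile genome ---
    insertions.sort(key=lambda x: x[0])
    parts: list[str] = []
    prev = 0
    offset_at: list[tuple[int, int]] = []  # (backbone pos, cumulative inserted bp)
    cum = 0
    for pos, seq, kind, meta in insertions:
        parts.append("".join(sterile_base[prev:pos]))
        parts.append(seq)
        cum_before = cum
        cum += len(seq)
        offset_at.append((pos, cum_before))
        prev = pos
    parts.append("".join(sterile_base[prev:]))
    sterile_seq = "".join(parts)

    def shift(x: int) -> int:
        """Backbone 0-based position -> final sterile 0-based position."""
        off = 0
        for pos, seq, kind, meta in insertions:
            if pos <= x:
                off += len(seq)
            else:
                break
        return x + off

    def insertion_final_start(pos: int) -> int:
        off = 0
        for p2, seq, kind, meta in insertions:
            if p2 < pos:
                off += len(seq)
            elif p2 == pos:
                return pos + off
        raise AssertionError

    sterile_features = [
        GeneModel(
            gene_name=f.gene_name, category=f.category, strand=f.strand,
            exons=[Interval(shift(iv.start - 1) + 1, shift(iv.start - 1) + iv.length)
                   for iv in f.exons],
            copy_index=f.copy_index, complete_cds=f.complete_cds,
        )
        for f in features
    ]

    # --- truth records in final coordinates ---
    truth_repeats: list[TruthRepeat] = []
    for src, copy_positions, length, orientation in truth_repeats_raw:
        a0 = shift(src)
        a = Interval.from0(a0, a0 + length)
        for p, _ in copy_positions:
            b0 = insertion_final_start(p)
            b = Interval.from0(b0, b0 + length)
            lo, hi = (a, b) if a.start <= b.start else (b, a)
            truth_repeats.append(TruthRepeat(
                interval_a=lo, interval_b=hi, orientation=orientation, length=length,
            ))
    truth_uniques: list[TruthUnique] = []
    truth_orfs: list[TruthOrf] = []
    orf_container: list[tuple[TruthOrf, TruthUnique]] = []
    for idx, (pos, length, orf_parts, near) in enumerate(truth_unique_raw, start=1):
        u0 = insertion_final_start(pos)
        unique = TruthUnique(
            label=f"U{idx}", interval=Interval.from0(u0, u0 + length),
        )
        truth_uniques.append(unique)
        for off, olen, fragments, feature, _ in orf_parts:
            # coordinate-based feature name: the convention run_screen uses
            # to link count-table rows to screened ORFs
            orf = TruthOrf(
                feature=f"orf_{u0 + off + 1}_{u0 + off + olen}",
                interval=Interval.from0(u0 + off, u0 + off + olen),
                strand="+",
                fragments=fragments,
                unique_label=unique.label,
                near_gene=near,
            )
            truth_orfs.append(orf)
            orf_container.append((orf, unique))
    truth_uniques.sort(key=lambda u: u.interval.start)
    for i, u in enumerate(truth_uniques, start=1):
        u.label = f"U{i}"
    for orf, unique in orf_container:
        orf.unique_label = unique.label
    truth_orfs.sort(key=lambda o: o.interval.start)

    # --- substitution noise (sterile only, frame-aware inside planted ORFs) ---
    if spec.noise_rate > 0:
        seq_list = list(sterile_seq)
        orf_spans = [(o.interval.to0(), o.interval.start - 1) for o in truth_orfs]
        n_sub = rng.binomial(len(seq_list), spec.noise_rate)
        positions = rng.choice(len(seq_list), size=n_sub, replace=False)
        for x in positions:
            inside = next((sp for sp, start0 in orf_spans if sp[0] <= x < sp[1]), None)
            if inside is None:
                alts = [b for b in "ACGT" if b != seq_list[x]]
                seq_list[x] = alts[int(rng.integers(3))]
                continue
            s0, e0 = inside
            ci = (x - s0) // 3
            n_codons = (e0 - s0) // 3
            if ci == 0 or ci == n_codons - 1:
                continue  # keep start and stop codons intact
            alts = [b for b in "ACGT" if b != seq_list[x]]
            rng.shuffle(alts)
            for b in alts:
                c0 = s0 + 3 * ci
                codon = "".join(seq_list[c0:c0 + 3])
                k = x - c0
                cand = codon[:k] + b + codon[k + 1:]
                if cand not in _STOPS:
                    seq_list[x] = b
                    break
        sterile_seq = "".join(seq_list)

    ancestor = Mitogenome("ancestor", "".join(ancestor_seq), circular=True,
                          features=features)
    maintainer = Mitogenome("maintainer", "".join(maintainer_seq), circular=True,
                            features=[GeneModel(
                                gene_name=f.gene_name, category=f.category,
                                strand=f.strand, exons=list(f.exons),
                                copy_index=f.copy_index, complete_cds=f.complete_cds,
                            ) for f in features])
    sterile = Mitogenome("sterile", sterile_seq, circular=True,
                         features=sterile_features)

    # --- count tables ---
    from .expression import CountTable

    counts_spec: dict[str, tuple[float, float, float]] = {}
    near_genes = {o.near_gene for o in truth_orfs if o.near_gene}
    for f in features:
        if f.gene_name in near_genes:
            counts_spec[f.gene_name] = (500.0, 0.5, 4.0)
        else:
            counts_spec[f.gene_name] = (500.0, 1.0, 1.0)
    for o in truth_orfs:
        if o.near_gene:
            counts_spec[o.feature] = (250.0, 0.5, 4.0)
        else:
            counts_spec[o.feature] = (250.0, 0.25, 8.0)
    if spec.counts_spec:
        counts_spec.update(spec.counts_spec)
    feats = list(counts_spec)
    counts = {"A": {}, "B": {}, "F1": {}}
    expected_de: dict[str, dict[str, bool]] = {}
    for feat in feats:
        mean, fc_ba, fc_fa = counts_spec[feat]
        counts["A"][feat] = int(rng.poisson(mean))
        counts["B"][feat] = int(rng.poisson(mean * fc_ba))
        counts["F1"][feat] = int(rng.poisson(mean * fc_fa))
        expected_de[feat] = {
            "BA": fc_ba >= 2.0 or fc_ba <= 0.5,
            "FA": fc_fa >= 2.0 or fc_fa <= 0.5,
        }
    table = CountTable(features=feats, counts=counts)

    truth = TruthTable(
        repeats=truth_repeats,
        uniques=truth_uniques,
        orfs=truth_orfs,
        snps=snps,
        expected_de=expected_de,
    )
    return SimulationResult(
        ancestor=ancestor, sterile=sterile, maintainer=maintainer,
        counts=table, truth=truth,
    )
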