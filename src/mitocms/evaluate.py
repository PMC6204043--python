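"""Recovery scoring against planted truth: the synthetic acceptance surface.

Runs the detection stages on a simulated trio and scores precision/recall
of planted repeats, unique regions and chimeric ORFs against the truth
table. Mutation-free planting is scored at exact coordinates (the planting
is junction-guarded, so maximal detections must reproduce the planted
extents); noisy planting is scored by reciprocal-overlap matching.
"""

from __future__ import annotations

from dataclasses import dataclass

from .compare import unique_regions
from .config import DEFAULT_CONFIG, PipelineConfig
from .models import Interval, Mitogenome, OrfRecord
from .orfs import classify_chimera, extract_orfs, full_length_identity
from .refgenes import reference_dict
from .repeats import accounting, find_repeats
from .simulate import SimulationResult, SimulationSpec, simulate


@dataclass
class RecoveryScore:
    repeat_recall: float
    repeat_precision: float
    unique_recall: float
    unique_precision: float
    orf_recall: float
    orf_precision: float
    fragment_boundaries_exact: bool
    partition_holds: bool
    n_false_novel_backbone: int


def _overlap_frac(a: Interval, b: Interval) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return inter / max(a.length, b.length)


def _prf(found: list, truth: list, match) -> tuple[float, float]:
    recall = (
        sum(1 for t in truth if any(match(f, t) for f in found)) / len(truth)
        if truth else 1.0
    )
    precision = (
        sum(1 for f in found if any(match(f, t) for t in truth)) / len(found)
        if found else 1.0
    )
    return recall, precision


def score_recovery(
    res: SimulationResult,
    cfg: PipelineConfig = DEFAULT_CONFIG,
    exact: bool = True,
) -> RecoveryScore:
    """Detect and score planted repeats, unique regions and chimeric ORFs.

    ``exact=True`` (mutation-free planting) demands exact coordinates and an
    identity floor of 1.0 for repeats; otherwise matches count at >= 80%
    reciprocal overlap with the detection identity floor from the config.
    """
    sterile, maintainer, truth = res.sterile, res.maintainer, res.truth

    min_identity = 1.0 if exact else cfg.repeat_min_identity
    reps = find_repeats(sterile, cfg.min_repeat_len, min_identity)
    min_planted = min((t.length for t in truth.repeats), default=0)
    big = [r for r in reps if truth.repeats and r.length >= min_planted * 0.8]

    def rep_match(f, t):
        if exact:
            return (f.interval_a, f.interval_b, f.orientation) == \
                (t.interval_a, t.interval_b, t.orientation)
        return (f.orientation == t.orientation
                and _overlap_frac(f.interval_a, t.interval_a) >= 0.8
                and _overlap_frac(f.interval_b, t.interval_b) >= 0.8)

    rep_recall, rep_precision = _prf(big, truth.repeats, rep_match)

    uniq = unique_regions(sterile, [maintainer], cfg=cfg)

    def uniq_match(f, t):
        if exact:
            return (f.interval.start, f.interval.end) == \
                (t.interval.start, t.interval.end)
        return _overlap_frac(f.interval, t.interval) >= 0.8

    uniq_recall, uniq_precision = _prf(uniq, truth.uniques, uniq_match)

    refs = reference_dict()
    orfs = extract_orfs(sterile, cfg.orf_min_len, label_prefix="orf")
    chimeric: list[OrfRecord] = []
    n_false_novel = 0
    planted_ivs = (
        [t.interval for t in truth.uniques]
        + [t.interval_a for t in truth.repeats]
        + [t.interval_b for t in truth.repeats]
    )
    for o in orfs:
        o.novel = full_length_identity(o.sequence, maintainer) < cfg.novelty_identity
        if not o.novel:
            continue
        touches_planted = any(iv.overlaps(o.interval) for iv in planted_ivs)
        if not touches_planted and truth.match_orf(o.interval) is None:
            # an ORF drawn purely from the shared ancestral backbone must
            # never look novel (junction-spanning ORFs are genuinely novel)
            n_false_novel += 1
        classify_chimera(o, refs, sterile.features, cfg)
        if o.chimeric:
            chimeric.append(o)

    def orf_match(f, t):
        """Recall match: the planted ORF itself was found."""
        if exact:
            if (f.interval.start, f.interval.end) != (t.interval.start, t.interval.end):
                return False
        elif _overlap_frac(f.interval, t.interval) < 0.8:
            return False
        return any(
            frag.gene == tf.gene for frag in f.gene_fragments for tf in t.fragments
        )

    def frag_genomic(orf: OrfRecord, frag) -> Interval:
        if orf.strand == "+":
            return Interval(orf.interval.start + frag.orf_interval.start - 1,
                            orf.interval.start + frag.orf_interval.end - 1)
        return Interval(orf.interval.end - frag.orf_interval.end + 1,
                        orf.interval.end - frag.orf_interval.start + 1)

    def detection_match(f, t):
        """Precision match: a chimeric call is true when its gene fragment
        footprint coincides with a planted fragment (ORFs in other frames or
        on the antisense strand legitimately contain the same fragment)."""
        for frag in f.gene_fragments:
            fg = frag_genomic(f, frag)
            for tf in t.fragments:
                tg = Interval(t.interval.start + tf.orf_interval.start - 1,
                              t.interval.start + tf.orf_interval.end - 1)
                if frag.gene == tf.gene and fg.overlaps(tg):
                    return True
        return False

    orf_recall = (
        sum(1 for t in truth.orfs if any(orf_match(f, t) for f in chimeric))
        / len(truth.orfs) if truth.orfs else 1.0
    )
    orf_precision = (
        sum(1 for f in chimeric if any(detection_match(f, t) for t in truth.orfs))
        / len(chimeric) if chimeric else 1.0
    )

    fragments_exact = True
    if exact:
        for t in truth.orfs:
            hit = next((f for f in chimeric if orf_match(f, t)), None)
            if hit is None:
                fragments_exact = False
                continue
            for tf in t.fragments:
                ok = any(
                    frag.gene == tf.gene
                    and (frag.orf_interval.start, frag.orf_interval.end)
                    == (tf.orf_interval.start, tf.orf_interval.end)
                    for frag in hit.gene_fragments
                )
                fragments_exact = fragments_exact and ok

    acct = accounting(sterile, reps, cfg.dup_fragment_min)
    partition = acct.duplication_length + acct.backbone_length == len(sterile)
    return RecoveryScore(
        repeat_recall=rep_recall, repeat_precision=rep_precision,
        unique_recall=uniq_recall, unique_precision=uniq_precision,
        orf_recall=orf_recall, orf_precision=orf_precision,
        fragment_boundaries_exact=fragments_exact,
        partition_holds=partition,
        n_false_novel_backbone=n_false_novel,
    )


def recovery_over_seeds(
    seeds: list[int],
    noise_rate: float = 0.0,
    cfg: PipelineConfig = DEFAULT_CONFIG,
    spec_kwargs: dict | None = None,
) -> list[RecoveryScore]:
    out = []
    for seed in seeds:
        spec = SimulationSpec(seed=seed, noise_rate=noise_rate,
                              **(spec_kwargs or {}))
        out.append(score_recovery(simulate(spec), cfg, exact=noise_rate == 0.0))
    return out
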