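"""Run orchestration: the full CMS screen from genomes to ranked candidates."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .compare import annotate_unique_regions, anchor_chain, snp_sites, unique_regions
from .config import DEFAULT_CONFIG, PipelineConfig
from .expression import CountTable, analyze
from .models import (
    CandidateReport, ExpressionResult, GeneRates, Mitogenome, OrfRecord,
    RepeatAccounting, RepeatPair, SyntenyBlock, UniqueRegion, VariantSite,
)
from .orfs import screen_orfs
from .rank import rank_candidates
from .repeats import accounting, find_repeats, predict_molecules
from .variants import classify_all, ng86_kaks

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    sterile: Mitogenome
    maintainer: Mitogenome
    repeats: list[RepeatPair]
    accounting: RepeatAccounting
    blocks: list[SyntenyBlock]
    uniques: list[UniqueRegion]
    orfs: list[OrfRecord]
    variants: list[VariantSite]
    rates: list[GeneRates]
    expression: dict[str, ExpressionResult] | None
    candidates: CandidateReport
    molecules: list = field(default_factory=list)

    def as_report_dict(self, cfg: PipelineConfig, seed: int | None = None) -> dict:
        return {
            "genome": self.sterile, "orfs": self.orfs, "repeats": self.repeats,
            "uniques": self.uniques, "blocks": self.blocks,
            "variants": self.variants, "rates": self.rates,
            "expression": self.expression, "candidates": self.candidates,
            "accounting": self.accounting, "config": cfg, "seed": seed,
        }


def run_screen(
    sterile: Mitogenome,
    maintainer: Mitogenome,
    refs: dict[str, str],
    restorer: Mitogenome | None = None,
    counts: CountTable | None = None,
    cfg: PipelineConfig = DEFAULT_CONFIG,
    orf_prefix: str = "Aorf",
    expression_features: dict[str, str] | None = None,
) -> PipelineResult:
    """The complete screen of one sterile line against its maintainer.

    Stages: repeats and duplication accounting on the sterile genome;
    synteny and unique regions against the maintainer (and restorer when
    given); the six-frame ORF screen with novelty, chimera, grouping and TM
    evidence; coding SNPs and per-gene Ka/Ks from the maintainer-referenced
    alignment; expression contrasts when a count table is given; and the
    final candidate ranking. ``expression_features`` optionally maps ORF
    labels (as assigned during the screen) to count-table feature names.
    """
    annotation = sterile.features
    if not annotation:
        logger.warning("sterile genome has no annotation; screening context limited")
    repeats = find_repeats(sterile, cfg.min_repeat_len, cfg.repeat_min_identity)
    acct = accounting(sterile, repeats, cfg.dup_fragment_min)
    molecules = predict_molecules(sterile, repeats, cfg.large_repeat_min) \
        if sterile.circular else []
    blocks = anchor_chain(sterile, maintainer, cfg.synteny_anchor, cfg=cfg)
    others = [maintainer] + ([restorer] if restorer is not None else [])
    uniques = unique_regions(sterile, others, cfg=cfg)
    orfs = screen_orfs(sterile, maintainer, refs, annotation, uniques, repeats,
                       cfg, label_prefix=orf_prefix)
    annotate_unique_regions(uniques, blocks, orfs)

    variants = classify_all(snp_sites(
        maintainer, {sterile.name: sterile}, maintainer.features or None, cfg,
    )) if maintainer.features else []
    rates: list[GeneRates] = []
    if maintainer.features and sterile.features:
        sterile_by_gene = {
            (f.gene_name, f.copy_index): f for f in sterile.features
        }
        for f in maintainer.features:
            if not f.complete_cds and f.category in ("tRNA", "rRNA"):
                continue
            mate = sterile_by_gene.get((f.gene_name, f.copy_index))
            if mate is None or mate.cds_length != f.cds_length:
                continue
            try:
                rates.append(ng86_kaks(
                    f.extract_cds(maintainer.sequence),
                    mate.extract_cds(sterile.sequence),
                    gene=f.gene_name,
                ))
            except ValueError:
                continue

    expr = None
    if counts is not None:
        expr = analyze(counts, cfg)
        # count features named orf_<start>_<end> attach to screened ORFs by
        # coordinates; an explicit expression_features mapping overrides
        by_interval = {
            (o.interval.start, o.interval.end): o.label for o in orfs
        }
        for feature in list(expr):
            if feature.startswith("orf_"):
                parts = feature.split("_")
                if len(parts) == 3 and parts[1].isdigit() and parts[2].isdigit():
                    label = by_interval.get((int(parts[1]), int(parts[2])))
                    if label is not None:
                        expr[label] = expr[feature]
        if expression_features:
            for label, feature in expression_features.items():
                if feature in expr:
                    expr[label] = expr[feature]
    report = rank_candidates(orfs, expr, cfg)
    return PipelineResult(
        sterile=sterile, maintainer=maintainer, repeats=repeats,
        accounting=acct, blocks=blocks, uniques=uniques, orfs=orfs,
        variants=variants, rates=rates, expression=expr, candidates=report,
        molecules=molecules,
    )
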