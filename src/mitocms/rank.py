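"""Evidence integration: rank novel ORFs as CMS candidates.

Each novel ORF is scored on the screening criteria as an unweighted flag
count; the "candidate" marker preserves the successive-filter logic of the
screen: (chimeric OR in a unique region) AND near a same-direction
functional gene AND expression-concordant with that gene. The score only
orders the output; ties break by genomic position, so identical inputs give
byte-identical reports.
"""

from __future__ import annotations

from .config import DEFAULT_CONFIG, PipelineConfig
from .expression import concordance
from .models import CandidateEntry, CandidateReport, ExpressionResult, OrfRecord

import logging

logger = logging.getLogger(__name__)

FLAG_NAMES = (
    "novel", "chimeric", "group1_proximity", "tm_present", "repeat_boundary",
    "unique_region", "expression_concordant", "elevated_in_sterile",
)


def rank_candidates(
    orfs: list[OrfRecord],
    expr: dict[str, ExpressionResult] | None,
    cfg: PipelineConfig = DEFAULT_CONFIG,
) -> CandidateReport:
    """Score every novel ORF on the evidence flags and rank the list."""
    entries: list[CandidateEntry] = []
    if expr is None:
        logger.warning("no expression data; expression flags left unset")
    for orf in orfs:
        if not orf.novel:
            continue
        flags: dict[str, bool | None] = {
            "novel": True,
            "chimeric": orf.chimeric,
            "group1_proximity": (
                orf.nearest_gene is not None
                and orf.nearest_gene[1] <= cfg.proximity_max
                and orf.nearest_gene[2]
            ),
            "tm_present": orf.tm_domains > 0,
            "repeat_boundary": orf.at_repeat_boundary,
            "unique_region": orf.in_unique_region is not None,
        }
        if expr is not None and orf.label in expr and orf.nearest_gene is not None \
                and orf.nearest_gene[0] in expr:
            orf_res = expr[orf.label]
            nb_res = expr[orf.nearest_gene[0]]
            flags["expression_concordant"] = concordance(
                orf_res, nb_res, cfg.trend_zero_band,
            )
            flags["elevated_in_sterile"] = (
                orf_res.de_flag_BA and orf_res.log2fc_BA < 0
            )
        else:
            flags["expression_concordant"] = None
            flags["elevated_in_sterile"] = None
        score = sum(1 for v in flags.values() if v is True)
        is_candidate = (
            (flags["chimeric"] is True or flags["unique_region"] is True)
            and flags["group1_proximity"] is True
            and flags["expression_concordant"] is True
        )
        entries.append(CandidateEntry(
            label=orf.label,
            flags=flags,
            score=score,
            rank=0,
            is_candidate=is_candidate,
            position=orf.interval.start,
        ))
    entries.sort(key=lambda e: (-e.score, e.position, e.label))
    for i, e in enumerate(entries, start=1):
        e.rank = i
    return CandidateReport(entries=entries)
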