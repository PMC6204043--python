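"""Reading and writing: FASTA/GenBank input, GFF3/TSV/JSON output, annotation transfer."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .config import DEFAULT_CONFIG, PipelineConfig
from .homology import find_local_matches, merge_spans
from .models import GeneModel, Interval, Mitogenome

logger = logging.getLogger(__name__)

_CATEGORY_BY_PREFIX = (
    ("nad", "complex I"), ("sdh", "complex II"), ("cob", "complex III"),
    ("cox", "complex IV"), ("atp", "complex V"), ("ccm", "cytochrome c"),
    ("rpl", "ribosomal"), ("rps", "ribosomal"), ("rrn", "rRNA"),
    ("trn", "tRNA"), ("matr", "maturase"),
)


def gene_category(name: str) -> str:
    low = name.lower()
    for prefix, cat in _CATEGORY_BY_PREFIX:
        if low.startswith(prefix):
            return cat
    return "other"


def load_genome(path: str | Path, format: str = "fasta") -> Mitogenome:
    """Load a mitogenome from a FASTA or GenBank flat file.

    FASTA input yields an empty feature list; GenBank gene/CDS/tRNA/rRNA
    features are mapped to gene models. The sequence is uppercased and must
    contain only A/C/G/T/N.
    """
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        record = next(SeqIO.parse(str(path), format))
    except StopIteration:
        raise ValueError(f"{path}: no records found") from None
    seq = str(record.seq).upper()
    if not seq:
        raise ValueError(f"{path}: empty sequence")
    features: list[GeneModel] = []
    circular = True
    if format == "genbank":
        topology = record.annotations.get("topology", "circular")
        circular = topology == "circular"
        copy_count: dict[str, int] = {}
        seen_spans: set[tuple[str, int, int]] = set()
        for feat in record.features:
            if feat.type not in ("gene", "CDS", "tRNA", "rRNA"):
                continue
            name = (feat.qualifiers.get("gene") or feat.qualifiers.get("product")
                    or [feat.type])[0]
            exons = []
            for part in feat.location.parts:
                exons.append(Interval(int(part.start) + 1, int(part.end)))
            span_key = (name, exons[0].start, exons[-1].end)
            if span_key in seen_spans:
                continue  # gene + CDS pairs describe the same locus
            seen_spans.add(span_key)
            copy_count[name] = copy_count.get(name, 0) + 1
            try:
                features.append(GeneModel(
                    gene_name=name,
                    category=gene_category(name),
                    strand="-" if feat.location.strand == -1 else "+",
                    exons=exons,
                    copy_index=copy_count[name],
                ))
            except ValueError as exc:
                logger.warning("skipping feature %s: %s", name, exc)
    return Mitogenome(
        name=record.id or path.stem, sequence=seq, circular=circular,
        features=features,
    )


def write_fasta(genome: Mitogenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, len(genome.sequence), width):
            fh.write(genome.sequence[i:i + width] + "\n")


def load_reference_fasta(path: str | Path) -> dict[str, str]:
    """Reference gene FASTA as name -> uppercased sequence."""
    refs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        refs[rec.id] = str(rec.seq).upper()
    if not refs:
        raise ValueError(f"{path}: no reference sequences")
    return refs


def annotate_by_reference(
    genome: Mitogenome,
    refs: dict[str, str],
    cfg: PipelineConfig = DEFAULT_CONFIG,
) -> Mitogenome:
    """Transfer gene models onto a genome by homology to reference genes.

    A hit qualifies when identity >= cp_identity and its length reaches half
    the reference length; overlapping hits of one gene are merged, and each
    disjoint placement gets its own copy_index, ordered along the genome.
    """
    if not refs:
        raise ValueError("reference gene set is empty")
    features: list[GeneModel] = []
    any_hit = False
    for name, ref_seq in refs.items():
        min_len = max(16, len(ref_seq) // 2)
        try:
            alns = find_local_matches(
                genome.sequence, ref_seq, min_len=min_len,
                min_identity=cfg.cp_identity, max_evalue=cfg.homology_evalue_max,
            )
        except ValueError:
            continue
        if not alns:
            continue
        any_hit = True
        by_strand: dict[str, list] = {"+": [], "-": []}
        for a in alns:
            by_strand[a.strand].append(a.query_interval.to0())
        placements: list[tuple[Interval, str]] = []
        for strand, spans in by_strand.items():
            for iv in merge_spans(spans):
                placements.append((iv, strand))
        placements.sort(key=lambda p: p[0].start)
        for copy_index, (iv, strand) in enumerate(placements, start=1):
            features.append(GeneModel(
                gene_name=name, category=gene_category(name), strand=strand,
                exons=[iv], copy_index=copy_index,
            ))
    if not any_hit:
        logger.warning("%s: no reference gene hits at all; genome left unannotated",
                       genome.name)
        return genome
    features.sort(key=lambda f: f.span.start)
    return Mitogenome(
        name=genome.name, sequence=genome.sequence, circular=genome.circular,
        features=features,
    )


# ---------------------------------------------------------------------------
# report writing

_GFF_HEADER = "##gff-version 3\n"


def _gff_line(seqid, source, ftype, start, end, score, strand, attrs) -> str:
    attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
    return f"{seqid}\t{source}\t{ftype}\t{start}\t{end}\t{score}\t{strand}\t.\t{attr_s}\n"


def write_report(results: dict, outdir: str | Path) -> list[Path]:
    """Write the full analysis report: GFF3, TSV tables and a JSON summary.

    ``results`` may contain any of: genome (Mitogenome), orfs, repeats,
    uniques, blocks, variants, rates, expression (dict), candidates
    (CandidateReport), accounting, config (PipelineConfig), seed.
    Unknown keys are ignored; every emitted coordinate is 1-based inclusive
    with start <= end.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc
    written: list[Path] = []
    genome = results.get("genome")
    seqid = genome.name if genome is not None else "genome"
    gl = len(genome) if genome is not None else None

    def clamp(start: int, end: int) -> tuple[int, int]:
        # origin-wrapping intervals (end > genome length) are clipped for GFF3
        if gl is not None and end > gl:
            end = gl
        return start, end

    gff = outdir / "annotations.gff3"
    with open(gff, "w") as fh:
        fh.write(_GFF_HEADER)
        if genome is not None:
            for f in genome.features:
                for iv in f.exons:
                    s, e = clamp(iv.start, iv.end)
                    fh.write(_gff_line(seqid, "mitocms", "gene", s, e, ".", f.strand, {
                        "ID": f"{f.gene_name}.{f.copy_index}",
                        "Name": f.gene_name, "category": f.category,
                    }))
        for o in results.get("orfs", []):
            s, e = clamp(o.interval.start, o.interval.end)
            fh.write(_gff_line(seqid, "mitocms", "ORF", s, e, ".", o.strand, {
                "ID": o.label, "novel": str(bool(o.novel)).lower(),
                "chimeric": str(o.chimeric).lower(),
            }))
        for i, p in enumerate(results.get("repeats", []), start=1):
            for which, iv in (("a", p.interval_a), ("b", p.interval_b)):
                s, e = clamp(iv.start, iv.end)
                fh.write(_gff_line(
                    seqid, "mitocms", "dispersed_repeat", s, e, ".", "+", {
                        "ID": f"rep{i}{which}", "pair": f"rep{i}",
                        "orientation": p.orientation,
                        "identity": f"{p.identity:.4f}",
                    }))
        for u in results.get("uniques", []):
            s, e = clamp(u.interval.start, u.interval.end)
            fh.write(_gff_line(seqid, "mitocms", "unique_region", s, e, ".", "+", {
                "ID": u.label,
            }))
        for b in results.get("blocks", []):
            s, e = clamp(b.interval_a.start, b.interval_a.end)
            fh.write(_gff_line(seqid, "mitocms", "synteny_block", s, e,
                               f"{b.identity:.4f}", b.strand, {"ID": b.label}))
    written.append(gff)

    variants = results.get("variants")
    if variants is not None:
        rows = []
        for v in variants:
            row = {
                "gene": v.gene, "cds_position": v.cds_position,
                "codon_position": v.codon_position,
                "effect": v.effect, "mutation_class": v.mutation_class,
            }
            for g, c in v.codons.items():
                row[f"codon_{g}"] = c
                row[f"aa_{g}"] = v.amino_acids.get(g, "")
            rows.append(row)
        p = outdir / "variants.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        written.append(p)

    rates = results.get("rates")
    if rates is not None:
        p = outdir / "gene_rates.tsv"
        pd.DataFrame([
            {"gene": r.gene, "ka": r.ka, "ks": r.ks,
             "ka_ks": r.ratio if r.ratio is not None else "NA"}
            for r in rates
        ]).to_csv(p, sep="\t", index=False)
        written.append(p)

    uniques = results.get("uniques")
    if uniques is not None:
        p = outdir / "unique_regions.tsv"
        pd.DataFrame([
            {"label": u.label, "start": u.interval.start, "end": u.interval.end,
             "length": u.length,
             "flanking_blocks": "-".join(x for x in u.neighbor_blocks if x),
             "predicted_orfs": ",".join(u.contained_orfs)}
            for u in uniques
        ]).to_csv(p, sep="\t", index=False)
        written.append(p)

    orfs = results.get("orfs")
    if orfs is not None:
        p = outdir / "orfs.tsv"
        pd.DataFrame([
            {
                "label": o.label, "start": o.interval.start, "end": o.interval.end,
                "strand": o.strand, "length": o.length,
                "novel": o.novel, "chimeric": o.chimeric,
                "maintainer_coverage": (
                    round(o.maintainer_coverage, 3)
                    if o.maintainer_coverage is not None else "NA"),
                "group": o.group if o.group is not None else "NA",
                "tm_domains": o.tm_domains,
                "nearest_gene": o.nearest_gene[0] if o.nearest_gene else "NA",
                "nearest_gene_distance": o.nearest_gene[1] if o.nearest_gene else "NA",
                "unique_region": o.in_unique_region or "NA",
                "repeat_boundary": o.at_repeat_boundary,
                "gene_fragments": ";".join(
                    f"{f.gene}:{f.gene_interval.start}-{f.gene_interval.end}"
                    f"({f.length}bp,{f.identity:.2f})"
                    for f in o.gene_fragments),
            }
            for o in orfs
        ]).to_csv(p, sep="\t", index=False)
        written.append(p)

    accounting = results.get("accounting")
    if accounting is not None:
        p = outdir / "repeat_spectrum.tsv"
        pd.DataFrame([
            {"bin": label, "n_pairs": n, "total_bp": bp}
            for label, (n, bp) in accounting.spectrum.items()
        ]).to_csv(p, sep="\t", index=False)
        written.append(p)

    expression = results.get("expression")
    if expression is not None:
        from .expression import results_frame
        p = outdir / "expression.tsv"
        results_frame(expression).to_csv(p, sep="\t", index=False)
        written.append(p)

    candidates = results.get("candidates")
    if candidates is not None:
        p = outdir / "candidates.tsv"
        pd.DataFrame([
            {"label": e.label, "rank": e.rank, "score": e.score,
             "candidate": e.is_candidate,
             **{k: ("NA" if v is None else v) for k, v in e.flags.items()}}
            for e in candidates.entries
        ]).to_csv(p, sep="\t", index=False)
        written.append(p)
        pj = outdir / "evidence_matrix.json"
        pj.write_text(json.dumps({
            e.label: {"rank": e.rank, "score": e.score,
                      "candidate": e.is_candidate, "flags": e.flags}
            for e in candidates.entries
        }, indent=1))
        written.append(pj)

    summary = {
        "seed": results.get("seed"),
        "config": results["config"].to_dict() if "config" in results else None,
        "genome": {
            "name": seqid, "length": gl,
            "n_features": len(genome.features) if genome is not None else None,
        },
        "counts": {
            "orfs": len(results.get("orfs") or []),
            "repeats": len(results.get("repeats") or []),
            "unique_regions": len(results.get("uniques") or []),
            "synteny_blocks": len(results.get("blocks") or []),
            "variant_sites": len(results.get("variants") or []),
        },
    }
    if accounting is not None:
        summary["repeat_accounting"] = {
            "genome_length": accounting.genome_length,
            "duplication_length": accounting.duplication_length,
            "backbone_length": accounting.backbone_length,
            "duplication_fraction": accounting.duplication_fraction,
            "n_fragments": accounting.n_fragments,
        }
    p = outdir / "run_summary.json"
    p.write_text(json.dumps(summary, indent=1))
    written.append(p)
    return written


def load_run_summary(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
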