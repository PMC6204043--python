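"""Synthetic stand-in reference gene set for the cotton mitochondrial genes.

The pipeline's annotation transfer and chimera detection work against a
named set of mitochondrial gene sequences. The real cotton reference genes
are not redistributable inside this package, so this module generates a
*synthetic* stand-in set deterministically: the gene names, functional
categories and coding lengths match the cotton mitogenome gene complement
(36 protein genes, 3 rRNAs, a selection of tRNAs), but the sequences are
random sense-codon DNA fixed by an internal seed. Every analysis in the
package is relative — genes are planted into synthetic genomes from this
same set — so the stand-in is fully functional for testing and simulation.
Users analysing real genomes supply their own reference FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

_REFSEED = 714025  # fixed: the reference set is identical across runs

# name -> (category, CDS length in bp). Protein lengths follow typical cotton
# mitochondrial CDS sizes; all are multiples of 3 (ATG...stop included).
_PROTEIN_GENES = {
    "nad1": ("complex I", 978), "nad2": ("complex I", 1467),
    "nad3": ("complex I", 357), "nad4": ("complex I", 1488),
    "nad4L": ("complex I", 303), "nad5": ("complex I", 2013),
    "nad6": ("complex I", 618), "nad7": ("complex I", 1185),
    "nad9": ("complex I", 573),
    "sdh3": ("complex II", 435), "sdh4": ("complex II", 420),
    "cob": ("complex III", 1182),
    "cox1": ("complex IV", 1593), "cox2": ("complex IV", 783),
    "cox3": ("complex IV", 798),
    "atp1": ("complex V", 1521), "atp4": ("complex V", 585),
    "atp6": ("complex V", 1161), "atp8": ("complex V", 465),
    "atp9": ("complex V", 225),
    "ccmB": ("cytochrome c", 621), "ccmC": ("cytochrome c", 753),
    "ccmFC": ("cytochrome c", 1323), "ccmFN": ("cytochrome c", 1734),
    "rpl2": ("ribosomal", 1005), "rpl5": ("ribosomal", 582),
    "rpl10": ("ribosomal", 489), "rpl16": ("ribosomal", 435),
    "rps3": ("ribosomal", 1707), "rps4": ("ribosomal", 1098),
    "rps7": ("ribosomal", 447), "rps10": ("ribosomal", 333),
    "rps12": ("ribosomal", 378), "rps14": ("ribosomal", 303),
    "mttB": ("other", 804), "matR": ("maturase", 1968),
}
_RNA_GENES = {
    "rrn5": ("rRNA", 120), "rrn18": ("rRNA", 1950), "rrn26": ("rRNA", 3360),
    "trnM": ("tRNA", 73), "trnD": ("tRNA", 74), "trnE": ("tRNA", 72),
    "trnF": ("tRNA", 73), "trnC": ("tRNA", 71),
}

_STOPS = ("TAA", "TAG", "TGA")
_SENSE = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]
_SENSE_NO_ATG = [c for c in _SENSE if c != "ATG"]


@dataclass(frozen=True)
class RefGene:
    name: str
    category: str
    sequence: str

    @property
    def is_protein(self) -> bool:
        return self.category not in ("tRNA", "rRNA")


def random_cds(rng: np.random.Generator, length: int, include_atg: bool = True) -> str:
    """Stop-free random coding sequence of `length` bp (multiple of 3)."""
    if length % 3:
        raise ValueError("CDS length must be a multiple of 3")
    n = length // 3 - 2
    body = "".join(rng.choice(_SENSE_NO_ATG, size=max(n, 0)))
    start = "ATG" if include_atg else str(rng.choice(_SENSE_NO_ATG))
    return start + body + str(rng.choice(list(_STOPS)))


def reference_genes() -> list[RefGene]:
    """The deterministic synthetic reference gene set."""
    rng = np.random.default_rng(_REFSEED)
    genes: list[RefGene] = []
    for name, (cat, length) in _PROTEIN_GENES.items():
        genes.append(RefGene(name=name, category=cat, sequence=random_cds(rng, length)))
    for name, (cat, length) in _RNA_GENES.items():
        seq = "".join(rng.choice(list("ACGT"), size=length))
        genes.append(RefGene(name=name, category=cat, sequence=seq))
    return genes


def reference_dict(genes: list[RefGene] | None = None) -> dict[str, str]:
    return {g.name: g.sequence for g in (genes or reference_genes())}


def write_fasta(path: str | Path, genes: list[RefGene] | None = None) -> None:
    genes = genes or reference_genes()
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.name} {g.category} synthetic\n")
            for i in range(0, len(g.sequence), 70):
                fh.write(g.sequence[i:i + 70] + "\n")
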