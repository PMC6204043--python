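"""Expression contrasts from per-feature read-count tables.

The design has one library per condition (CMS line "A", maintainer "B" and
the fertility-restored F1), so differential calls use a count-based exact
test: a two-sided exact binomial of one feature's counts in two libraries
against the library-size proportion. Fold changes are reported as log2
ratios of counts-per-million with a pseudocount that guards zeros; the
pseudocount affects the displayed fold change only, not the test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import binomtest

from .config import DEFAULT_CONFIG, PipelineConfig
from .models import ExpressionResult

LIBRARIES = ("A", "B", "F1")  # CMS, maintainer, fertility-restored F1


@dataclass
class CountTable:
    features: list[str]
    counts: dict[str, dict[str, int]]  # library -> feature -> count
    library_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate feature labels")
        for lib, col in self.counts.items():
            if any(v < 0 for v in col.values()):
                raise ValueError(f"negative count in library {lib}")
            total = sum(col.values())
            if lib in self.library_sizes:
                if self.library_sizes[lib] != total:
                    raise ValueError(f"library size of {lib} != column sum")
            else:
                self.library_sizes[lib] = total

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        required = ["feature", "count_A", "count_B", "count_F1"]
        if list(df.columns[:4]) != required:
            raise ValueError(f"count table must have columns {required}")
        features = df["feature"].astype(str).tolist()
        counts = {
            lib: dict(zip(features, df[f"count_{lib}"].astype(int)))
            for lib in LIBRARIES
        }
        return cls(features=features, counts=counts)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "feature": self.features,
            **{f"count_{lib}": [self.counts[lib][f] for f in self.features]
               for lib in LIBRARIES},
        })
        df.to_csv(path, sep="\t", index=False)


def log2fc(
    count_a: int,
    count_b: int,
    size_a: int,
    size_b: int,
    pseudocount: float = 0.5,
) -> float:
    """log2 of the normalized (counts-per-million) b-over-a ratio.

    ``log2fc(count_A, count_B, ...)`` is the log2 B/A contrast.
    """
    if size_a <= 0 or size_b <= 0:
        raise ValueError("library sizes must be positive")
    cpm_a = count_a / size_a * 1e6
    cpm_b = count_b / size_b * 1e6
    return math.log2(cpm_b + pseudocount) - math.log2(cpm_a + pseudocount)


def de_test(count_a: int, count_b: int, size_a: int, size_b: int) -> float:
    """Two-sided exact binomial p-value for count_a vs count_b.

    Tests count_a out of count_a + count_b against the library-size
    proportion size_a / (size_a + size_b). Both counts zero gives p = 1.
    """
    n = count_a + count_b
    if n == 0:
        return 1.0
    p0 = size_a / (size_a + size_b)
    return binomtest(count_a, n, p0, alternative="two-sided").pvalue


def analyze(
    table: CountTable,
    cfg: PipelineConfig = DEFAULT_CONFIG,
) -> dict[str, ExpressionResult]:
    """Per-feature B/A and F1/A contrasts with differential flags."""
    sizes = table.library_sizes
    log2_fold = math.log2(cfg.de_fold)
    out: dict[str, ExpressionResult] = {}
    for feat in table.features:
        a = table.counts["A"][feat]
        b = table.counts["B"][feat]
        f = table.counts["F1"][feat]
        fc_ba = log2fc(a, b, sizes["A"], sizes["B"], cfg.pseudocount)
        fc_fa = log2fc(a, f, sizes["A"], sizes["F1"], cfg.pseudocount)
        p_ba = de_test(a, b, sizes["A"], sizes["B"])
        p_fa = de_test(a, f, sizes["A"], sizes["F1"])
        out[feat] = ExpressionResult(
            feature=feat,
            log2fc_BA=fc_ba,
            log2fc_FA=fc_fa,
            pvalue_BA=p_ba,
            pvalue_FA=p_fa,
            de_flag_BA=abs(fc_ba) >= log2_fold and p_ba < cfg.de_alpha,
            de_flag_FA=abs(fc_fa) >= log2_fold and p_fa < cfg.de_alpha,
        )
    return out


def _trend_sign(x: float, zero_band: float) -> int:
    if abs(x) <= zero_band:
        return 0
    return 1 if x > 0 else -1


def concordance(
    orf: ExpressionResult,
    neighbor: ExpressionResult,
    zero_band: float = 0.25,
) -> bool:
    """Same expression trend in both contrasts (zero matches either sign).

    This is the co-transcription criterion: an ORF and its adjacent gene
    moving in the same direction in both the maintainer/CMS and F1/CMS
    contrasts is evidence of a shared transcript.
    """
    for a, b in (
        (orf.log2fc_BA, neighbor.log2fc_BA),
        (orf.log2fc_FA, neighbor.log2fc_FA),
    ):
        sa, sb = _trend_sign(a, zero_band), _trend_sign(b, zero_band)
        if sa != 0 and sb != 0 and sa != sb:
            return False
    return True


def results_frame(results: dict[str, ExpressionResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "feature": r.feature,
            "log2fc_BA": r.log2fc_BA,
            "log2fc_FA": r.log2fc_FA,
            "pvalue_BA": r.pvalue_BA,
            "pvalue_FA": r.pvalue_FA,
            "de_BA": r.de_flag_BA,
            "de_FA": r.de_flag_FA,
        }
        for r in results.values()
    ])
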