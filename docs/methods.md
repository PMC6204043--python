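# Methods

This note records the models, algorithmic choices and their rationale, what
the synthetic data do and do not emulate, and the package's known limits.

## Coordinates and circularity

Algorithms use 0-based half-open coordinates internally; every record type
and output file is 1-based inclusive with `start <= end` (strand carries
direction, GFF3-style). Circular genomes are stored linearized at the
deposited origin. Operations that must see origin-spanning features
(repeats, ORFs) scan the doubled sequence and reduce placements modulo the
genome length; a feature spanning the origin is reported with
`end > genome length`, and the GFF3 writer clips such intervals at the
origin.

## Local homology search

A seed–extend–chain nucleotide aligner stands in for a database BLASTN in
every context the pipeline needs (annotation transfer, unique-region
absence checks, chloroplast-derived filtering, chimeric-fragment mapping).
Exact 16-mer seeds are collapsed into diagonal runs, runs are chained when
close in both sequences (≤ 800 bp), candidates are extended ungapped with an
X-drop of 20, realigned exactly with edlib, and *every* maximal
positive-scoring stretch of alignment columns is reported (recursive
maximal-subsequence decomposition — a chained candidate spanning an
insertion breakpoint yields the homologous stretches on both sides, not
just the better one). Scoring is match +1, mismatch −2, gap open −5, gap
extend −2; significance uses `E = K·m·n·exp(−λ·score)` with fixed
approximate ungapped constants λ = 1.28, K = 0.46 for this scheme. These
constants are documented approximations: every pipeline filter also imposes
a length and identity floor, so the exactness of E is not load-bearing.
Identity is matches over alignment columns (gap columns count against
identity); N bases never match. Sub-alignments contained in a
higher-scoring reported alignment on the same strand are suppressed; equal
scores tie-break by smaller query start.

## Repeats

Repeat pairs are maximal with respect to the identity floor: both ends are
matches and extending either end keeps identity below the floor. With floor
1.0 this is the classical maximal exact repeat pair; the default floor 0.95
mirrors a < 5 % substitution tolerance. Mismatch-tolerant extension
considers substitutions only — diverged copies broken by indels appear as
separate pairs. The finder seeds on exact k-mers, extends each seed pair to
its maximal extent, and skips seeds already covered on their diagonal, so
every distinct maximal pair is reported exactly once (direct and inverted;
a perfect palindrome matching itself is excluded). "Palindromic reverse"
and "complemented" repeat classes are treated as the single biological
class of inverted (reverse-complement) repeats.

Duplication accounting merges overlapping fragments ≥ 500 bp, groups them
into families by single-linkage over the repeat pairs, and counts per
family the length of all copies less the longest one; backbone = genome −
duplication, which partitions the genome by construction. The size spectrum
(bins > 10 kb, 1–10 kb, 0.5–1 kb, 101–500, 41–100, 31–40 and ≤ 30 bp)
covers all pairs with no fragment floor; the lowest printed bin ("21–30")
also holds the 20 bp detection floor.

Molecule prediction: each direct repeat ≥ 1 kb yields the two subcircles
delimited by its copies (lengths sum to the parent length, each subcircle
retains one copy); each inverted repeat ≥ 1 kb yields one isomeric master
circle of unchanged length. Nested or overlapping large repeats are handled
independently with a logged warning.

## Synteny and unique regions

Synteny blocks chain maximal exact matches ≥ 50 bp collinearly per strand.
Junction gaps up to 5 kb are bridged in both genomes *except* when the two
gaps differ by more than the unique-region floor (300 bp) — a junction
implying an insertion that large is never bridged, which keeps blocks and
unique regions disjoint. A chain becomes a block when its spanned identity
(edlib edit distance over the longer span) reaches 98 %, recursively
splitting at the widest junction otherwise. Blocks are trimmed into a
non-overlapping tiling of the focal genome (longer blocks win; boundary
slivers from chance junction matches are trimmed), must reach the 100 bp
coverage floor (shorter matches — e.g. gene fragments inside unique
regions — are not syntenic regions), and are labeled S1..Sn along the
focal genome.

A unique region is a maximal focal interval ≥ 300 bp with no alignment of
≥ 90 % identity and ≥ 100 bp into any comparison genome. The qualifying
alignment is deliberately stricter than the chloroplast filter (30 bp) and
looser than novelty (99 %): absence is stated in the source method without
a numeric threshold, so the package fixes one and documents it here. The
300 bp region floor matches the ORF length floor, so any region that could
host a screened ORF is reportable.

## SNP sites and effects

Substitution columns are extracted from per-block edlib alignments of each
genome against a chosen reference (the maintainer by default); indel
columns are skipped, and codons with any unaligned position are emitted
with effect `unresolved`. Within annotated CDS, each variant codon carries
all genomes' codons (reading-order positions; minus-strand codons are
complemented in place, not reversed, because positions are already in
reading order). Effects: nonsynonymous iff ≥ 2 distinct residues,
nonsense when a stop appears in some but not all genomes, synonymous
otherwise; transition/transversion is judged reference base vs alternative
base (majority across alternatives; ties fall to transversion, the commoner
event in these genomes).

Ka/Ks follows Nei–Gojobori (1986): per-codon synonymous site fractions
(changes to stops count as nonsynonymous), difference counts averaged over
all minimal mutation paths that avoid stop codons (all paths used only if
every path is blocked), proportions corrected by Jukes–Cantor
`d = −¾·ln(1 − 4p/3)`. Ks = 0 leaves the ratio undefined (`None`), never
infinity. The implementation reproduces the independent NG86 implementation
in Biopython to 1e-9 on stop-free pairs (tested).

RNA-editing candidates are limited to chemically coherent C→U events: an
annotated ACG first codon (edited to AUG) and terminal codons one C→U from
a canonical stop (CGA→UGA, CAA→UAA, CAG→UAG). Editing events described in
other directions (U→G start repair, stop-to-sense conversions) are not
C→U chemistry and are out of scope.

## The ORF screen

ORFs run from the first ATG of a stop-delimited frame segment to the stop
codon inclusive (ORFfinder convention; `mode="stop2stop"` is available),
length includes the stop codon, and only the longest ORF per stop is
reported. Novelty uses infix (full-query) alignment of the ORF into the
maintainer genome on both strands: identity over alignment columns
≥ 99 % ⇒ not novel. The fractional maintainer coverage reported alongside
(local matches at ≥ 90 % / ≥ 30 bp) replaces the source tables'
"Some/partial" wording with a number. Chimera status requires a ≥ 30 bp
reference-gene fragment and no overlap with any annotated gene placement;
fragments are recorded with their positions in both the ORF and the gene.
Groups: (1) nearest functional gene — protein, rRNA or tRNA all qualify —
within 565 bp and same strand; (2) contained in a unique region; (3) mosaic,
operationalized as ≥ 30 bp of maintainer-homologous and ≥ 30 bp of
non-homologous sequence. The lowest applicable group is primary, the rest
are secondary flags. TM segments: Kyte–Doolittle means over 19-residue
windows ≥ 1.6; qualifying windows are merged where they overlap or abut,
and each merged stretch counts one segment per non-overlapping window it
can hold (30 consecutive Leu → 1, 60 → 3).

## Expression

One library per condition admits only count-based tests, so the
differential call is a two-sided exact binomial of a feature's two counts
against the library-size proportion (chi-squared would be the asymptotic
alternative; the exact test is correct at all counts). Both counts zero
gives p = 1. Fold changes are log2 ratios of counts-per-million with a 0.5
pseudocount for display; the test uses raw counts. The differential flag is
|log2FC| ≥ 1 and p < 0.05. Concordance between an ORF and its neighbor
gene: the trend signs must not conflict in either the maintainer/CMS or
F1/CMS contrast, with values within ±0.25 of zero matching either sign —
the zero band absorbs near-zero fold changes that would otherwise flip sign
by noise.

## Candidate ranking

Flags: novel, chimeric, group-1 proximity, TM present, repeat boundary
(an ORF end within 100 bp of a large-repeat edge), unique region,
expression concordance, elevated in the sterile line. The score is an
unweighted count of true flags and only orders output; candidacy itself is
the filter chain (chimeric or unique-region) ∧ group-1 proximity ∧
concordance. TM presence is evidence, not a gate — documented CMS factors
exist without predicted TM helices. Missing expression data leaves the two
expression flags unset (`None`) and the ORF scored on the rest. Ties break
by genomic position, so reports are byte-identical across runs.

## Synthetic data: what it emulates, and what it does not

The generator derives a sterile-like and a maintainer-like genome from a
common random ancestor (default 80 kb, GC 0.45 — desk-scale rather than the
~670 kb of real cotton mitogenomes; all thresholds are absolute bp, so
behavior transfers). The ancestor carries ~20 genes drawn from the
synthetic reference set. The maintainer differs from the ancestor only by
its own coding SNPs; the sterile genome additionally carries planted
repeats (default one 2 kb direct and one 1.2 kb inverted extra copy of
backbone segments), unique insertions with chimeric ORFs (default 3 kb with
a 45 bp gene fragment placed near a same-strand gene, and 2.4 kb with a
60 bp fragment far from genes), and its own SNPs (24 total, 75 %
nonsynonymous, at most one per ~300 bp of any gene — mirroring real
per-gene SNP sparsity and keeping shared backbone ORFs above the novelty
floor). Counts are Poisson with planted fold changes (candidate ORFs and
their neighbor genes move together: B/A = 0.5, F1/A = 4).

Planting is *junction-guarded*: inserted copies and insertions are placed
so the bases flanking every junction mismatch their counterparts (six
guarded bases at unique-insertion junctions; anti-aligned filler codons
after gene fragments). This makes the planted coordinates the exact
maximal extents a correct detector must report, so mutation-free recovery
is scored at exact coordinates. Optional substitution noise is frame-aware
inside planted ORFs (never creates an in-frame stop, never touches the
start or stop codon) — emulating coding constraint, and keeping "recall
under noise" a property of the detectors rather than of stop-codon
lotteries.

What passing these tests shows: the detectors find exactly what was
planted, with exact boundaries, under the stated thresholds, and degrade
gracefully at 1 % divergence. What they do not show: performance on real
mitogenomes with heteroplasmy, nested repeat families, RNA-editing-driven
annotation ambiguity, sequencing error, or reference gene sets diverged
from the sample — the bundled reference genes are synthetic stand-ins, and
real analyses must supply genuine references.

## Numerical and degenerate-input choices

* N bases mismatch everywhere and invalidate codons (`unresolved`).
* The E-value needs `score ≥ 0`; empty sequences are rejected, as is a
  search minimum below the seed size.
* Repeat accounting caps duplication at the genome length; an empty repeat
  list gives duplication 0 and backbone = genome.
* `ng86_kaks` rejects unequal lengths, non-multiples of 3 and internal
  stops; a shared terminal stop codon is skipped as a non-coding site.
* Proportions ≥ 3/4 under Jukes–Cantor return infinity; the ratio is then
  reported against it rather than silently clipped.
* ORFs with internal stops (possible only for hand-built records) are
  flagged `translation_error` and get TM count 0.
* The simulator raises `PlacementError` naming the first unplaceable event
  when a spec is too dense for its genome length; placement samples
  uniformly over feasible gaps and relaxes its separation margin before
  giving up.

## Problem sizes used in the test suite

Unit oracles run on 1–5 kb instances (brute-force all-pairs repeat oracle,
affine Smith–Waterman, regex six-frame ORF oracle, binomial summation,
Biopython NG86). Planted-truth recovery runs 25 seeds mutation-free plus 25
seeds at 1 % noise on the default 80 kb spec; the full-screen integration
tests use a 30 kb spec with proportionally smaller planted events. These
sizes were chosen so the whole suite exercises every stage at realistic
repeat/gene densities while remaining a routine desk run.

## Known limitations

* The homology search is tuned for high-identity homology (≥ ~85 %); remote
  similarity search is out of scope, as is protein-level (BLASTX-style)
  annotation — annotation transfer is nucleotide-only against the bundled
  or user-supplied gene set.
* Repeat extension tolerates substitutions but not indels; an indel inside
  a diverged repeat splits it into two reported pairs (the accounting
  merges overlapping fragments, so duplication totals are robust to this).
* Families are built by single-linkage; a repeat shared between two
  otherwise distinct families merges them, which can undercount duplication
  when families overlap ("copies − 1" is then applied to the merged set,
  with a logged warning).
* SNP extraction requires positions covered by a synteny block; variants in
  regions that fail block identity are not called.
* The expression model has no replicates and therefore no dispersion
  estimate; p-values are exact under Poisson-like sampling but
  anti-conservative under biological overdispersion.
* Restorer-side (nuclear Rf) analysis, read mapping, and assembly are out
  of scope; the pipeline consumes assembled genomes and count tables.
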