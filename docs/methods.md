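# Methods

This note documents the models and procedures implemented in
`straindiff`, the defaults and why they were chosen, what the synthetic
data does and does not emulate, and the numerical decisions that a user
comparing results against another toolchain will want to know.

## Alignment

### Seeding and chaining

Whole-genome and contig-to-reference alignment uses seed–chain–extend:

1. **Seeding.** All maximal exact matches (MEMs) of length ≥ `min_mem`
   (default 20 bp) are enumerated from an exact k-mer index with
   extension to maximality and per-diagonal deduplication. `N` never
   matches any base, including another `N` — ambiguity is treated
   conservatively. A 20 bp seed keeps seeding sensitive down to ~90%
   identity (the probability that a 20-mer survives untouched at 10%
   divergence is ~0.12, giving a seed every few hundred bases); screens
   that must discriminate near the 90% cut (conservation screen, mosaic
   painting) use 15 bp seeds.
2. **Chaining.** Collinear same-strand anchors are chained by dynamic
   programming with an affine join cost
   (`gap_open` 20 + 0.05·|indel| + 0.02·matched-gap length). Join limits:
   ≤ 1 kb on the smaller side of a junction and ≤ 20 kb on the larger, so
   a chain can span a structural deletion or insertion (a 6 kb transposon
   excision must remain inside one block for the gapped-alignment call)
   but not arbitrary rearrangements. Predecessor candidates are the
   nearest 60 anchors plus the current best-scoring anchors, so a primary
   chain bridges clutters of repeat-induced anchors. After one DP pass,
   chains are peeled off greedily by descending endpoint score; the
   secondary chains of repeated sequence are kept, because downstream
   ambiguity flagging is defined on them.
3. **Gap closing.** Anchors are emitted as literal match runs; only
   inter-anchor gaps are aligned (edlib, optimal unit cost). Strongly
   one-sided gaps (length ratio > 4 and difference > 200 bp) are closed
   as an indel with the smaller side placed by infix alignment inside the
   larger side. This anchor-pinned construction is deliberate: a plain
   unit-cost global alignment of a region containing a multi-kilobase
   deletion "threads" the deletion through accidental single-base matches
   (saving one edit per lucky base) and smears it into dozens of
   fragments, which would destroy both structural-gap detection and
   per-segment identity. Each block also records the true optimal
   unit-cost edit distance of its aligned region, computed independently
   of the pinned path.
4. **Refinement.** Near-identical neighborhoods (pointwise identity
   ≥ 0.90 after discounting gaps ≥ 100 bp) containing small gaps are
   re-aligned with affine gap costs (match 1, mismatch −1.5, open −3,
   extend −0.5) in windows padded by 25 matched columns. Unit-cost optima
   are non-unique and may split a 5 bp indel into scattered 1–2 bp
   pieces; affine refinement consolidates them, and left-alignment at
   call time makes the representation canonical.

Identity is matches / aligned columns, recomputable from the edit path.
A block is **ambiguous** iff more than half of its query interval is also
covered by other blocks with identity ≥ 0.95 — this operationalizes
"non-ambiguous mapping" and is query-sided on purpose: two query regions
mapping to one reference locus is reference-side redundancy, not mapping
ambiguity.

### Self-repeats

Repetitive reference regions are blocks of the genome-vs-itself alignment
(trivial diagonal excluded) with identity > 0.95 and span ≥ 500 bp,
emitted symmetrically. Transposon families and segmental duplications are
found this way; tandem arrays surface through their unit-shifted
self-alignments.

## Variant calling

Only non-ambiguous alignment segments with identity ≥ 0.97 contribute.
Blocks are split at gap runs > 90 bp before the identity filter is
applied, so a single structural gap does not disqualify an otherwise
near-identical alignment; those runs are reported separately as
structural events, never as small indels. Each mismatch column is one
SNV; each remaining gap run (1–90 bp) is one indel, left-normalized
through its repeat context (VCF convention). The 90 bp ceiling is a hard
invariant of the caller.

Tandem repeats are detected as maximal perfect arrays (unit ≤ 60 bp,
≥ 2 copies) by a vectorized shifted-equality scan; overlapping reports
merge by longest span with the smallest unit kept. At genome scale the
2-copy micro-arrays (any doubled dinucleotide) are ubiquitous, so the
pipeline applies an 8 bp minimum span for annotation purposes.

Gene effects: SNVs in CDS are classified by codon translation on the
coding strand (standard nuclear code, configurable); `sense` denotes
synonymous changes. In-CDS indels are `frameshift` iff length mod 3 ≠ 0,
else `inframe_indel`; any edit touching the first or last codon is
`start_stop_altered`. Mid-CDS stop gains are folded into `missense` (the
protein differs), matching a full-mutant-translation oracle; only edits
that destroy the annotated start or stop are `start_stop_altered`. Genes
whose CDS length is not a multiple of 3 are skipped with a warning.

## Copy-number analysis

Windows are 414 bp (the last partial window keeps its true width).
The depth ratio is library-size scaled and then normalized so the average
ratio per chromosome is 1; the alternative readings (normalize each track,
or no chromosome normalization) are selectable because the convention
differs between toolchains. Windows with zero reference count are flagged
and excluded from the normalization mean. The per-window two-sided
p-value uses the Geary–Hinkley transformation of a ratio of Poisson
counts with null ratio r₀ = 1; at ≥ ~50 reads per window the statistic is
close enough to normal that 10,000 null windows pass a KS uniformity test
at α = 0.01. Segments are maximal runs of ≥ 3 consecutive same-sign
windows with |log₂| ≥ 0.6 (the threshold conventional for this ratio
statistic); the 3-window minimum suppresses single-window Poisson
outliers. The −4 display cap on log₂ ratios applies at serialization
only, never to statistics.

## Assembly QC

Each contig gets one placement: the block maximizing aligned length ×
identity, ties to the lower reference coordinate (logged). Gaps between
consecutive placements are labeled from two independent flags: *missing
sequence* (≥ 1 base with zero read coverage — the data are absent) and
*unassembled* (overlap with a > 95%-identity self-repeat — the data exist
but assembly failed); both flags give `both`, neither `unexplained`.

Transposon loci are classified with precedence AS > GA > CB: AS requires a
spanning block with no gap ≥ 100 bp over the locus; GA a spanning block
with a deletion gap within ± 20% of the annotated element length (the
tolerance absorbs the solo-LTR remnant, ~5% of a 6 kb element, plus
alignment jitter); CB distinct contigs terminating within 1 kb of either
flank. Loci matching no pattern are conservatively `present_break` with a
warning. Per-family copy numbers are estimated as reference count ×
median per-element depth ratio, with ratios normalized by the genome-wide
median 1 kb-window ratio (robust to CNVs and to genome-size differences);
the median is taken on the linear scale, which equals 2^(median log₂)
for odd counts and stays defined when excised elements drive ratios to 0.

## Presence/absence and unique regions

`deleted_high_confidence` ⇔ absent from the assembly (no block covering
≥ 80% of the gene at ≥ 95% identity) AND depth-depleted (mean window log₂
< −0.6). The 80% coverage floor is this package's choice: an identity
threshold alone is meaningless for a block clipping 5% of a gene. Genes
absent from the assembly with normal depth are reported
`absent_in_assembly` only — the assembly-dropout failure mode the
intersection rule exists to exclude.

Unique regions apply best-alignment-per-reference-position filtering at
the segment level: segments (blocks split at ≥ 100 bp gaps) claim
reference positions in order of parent-chain length then identity, so the
collinear primary alignment keeps its position and the extra copy of a
duplication is left unexplained. Unclaimed query runs ≥ 500 bp are
unique; the 500 bp floor is configurable (the studies this mirrors report
multi-kb unique contigs). The conservation screen keeps strains whose
best local alignment has query coverage > 0.60 and identity > 0.90, both
strict.

## Comparison

Mosaic channels are clamp((best identity − 0.97)/0.03, 0, 1) per
1000 bp fragment and group; the best alignment is the top-scoring chain
with the fragment extended to its ends by infix alignment, so identity is
measured over the whole fragment. The coverage distance is
d = 1 − 2·C/(|A|+|B|) where C counts matching columns of reciprocally
best alignments at ≥ 90% identity, averaged over both directions so the
function is exactly symmetric. Counting matching columns rather than raw
aligned length is this package's reading of "coverage distance" (the
literature definition is not unique): raw length saturates once seeds
cover the genome, and distances between strains at 0.5% and 2% divergence
would collapse to ~0; matched-column mass keeps d equal to 0 on self,
1 on unrelated sequence, and strictly increasing in divergence. The
function is isolated so an alternative definition can be swapped in.

UPGMA uses size-weighted (proportional) averaging; merge ties break on
the lexicographically smallest label pair, and leaf heights are half the
merge distance, so trees are exactly ultrametric and ultrametric input
matrices are fixed points.

## Enrichment

EASE = one-sided hypergeometric upper tail with the observed overlap
reduced by one (P = 1 at k ≤ 1). The background defaults to the genes of
the supplied annotation map, not the whole genome — the convention of the
annotation tool this mirrors — and is overridable. Every category with
k ≥ 1 is tested; Bonferroni multiplies by the number tested. Under a
uniform-sampling null the score is conservative (empirical type-I error
well below nominal), which is its design intent.

## Synthetic data: what it emulates, and what it does not

The generator builds a compact yeast-like genome: 0.38 GC background,
genes (ATG + stop-free codons + stop, 300–1500 bp, ~1 per 2.5–3 kb,
~15% in subtelomeric blocks), Ty1–Ty5 elements (6 kb with 300 bp LTRs,
byte-identical within a family, ~1% body divergence between copies),
and perfect tandem arrays (unit 3–60 bp, 5–40 copies). The derived strain
carries ~0.2% SNVs and ~0.025% indels by default (the divergence scale of
two related laboratory strains), with 60% of indels inside tandem arrays
at unit-multiple lengths; structural classes (deletions, duplications,
excisions, novel insertions) are planted per plan. Depth is Poisson per
window at ~50× equivalent (414 expected reads per 414 bp window) with a
deterministic GC bias shared between the strains, so the ratio cancels
it exactly — by design, since the ratio statistic is the object under
test. Every operation is a pure function of (inputs, seed), with one
derived substream per stage.

Deliberately not modeled: sequencing errors and read-level artifacts
(depth is drawn directly, not from reads), diploidy and heterozygosity,
chromosomal rearrangements (inversions/translocations), GC bias that
*differs* between libraries, imperfect tandem arrays, and nested or
overlapping structural events (the planner rejects colliding edits).
Passing tests therefore demonstrate the correctness of the algorithms
under the stated model — clean Poisson depth, point-and-segment
variation on a stable karyotype — not robustness to real-library
artifacts such as mapping bias at paralogs, PCR duplicates, or
reference-bias in repeat annotation.

Problem sizes in the test suite and the acceptance script (0.1–0.8 Mb
genomes, 30 transposon loci, 10⁴ null windows, 10³ enrichment
replicates) are the package's chosen desk-scale study conditions; all
thresholds above are the analysis defaults, not tuned per dataset.

## Known limitations

- The aligner targets collinear, high-identity comparisons (strains of
  one species); it does not produce split/inversion alignments, and
  protein-level alignment is out of scope.
- Chain extraction after one DP pass is greedy; a secondary alignment
  that shares its best prefix with the primary chain may be truncated.
- `ref_to_query` projection is approximate within gap columns (exact at
  match columns), which can shift unique-region boundaries by a few
  bases around indels.
- The Geary–Hinkley normal approximation degrades below ~20 reads per
  window; window sizes should be chosen to keep expected counts above
  that.
- Gene-effect annotation handles single-CDS models (the generator's gene
  structure); multi-exon CDS inputs are accepted by the data model but
  splice-aware effects are not classified.
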