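"""SNV and small-indel calling from alignment blocks, tandem-repeat
detection, and gene-effect annotation.

Calls are made only from non-ambiguous blocks at >= 97% identity. Each
mismatch column yields one SNV; each gap run of length <= 90 bp yields one
indel; longer gap runs are structural events and are reported separately,
never as small indels. Indels are left-aligned within their repeat context
before reporting (VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .align import AlignmentBlock, split_blocks_at_large_gaps
from .io import GenomicInterval, GeneModel, revcomp

logger = logging.getLogger(__name__)

MAX_INDEL = 90


@dataclass
class VariantCall:
    """A called SNV or short indel on reference coordinates.

    ``pos`` is the 0-based reference offset of the variant itself (first
    deleted base for deletions; insertion point for insertions)."""

    kind: str  # snv | insertion | deletion
    seq_id: str
    pos: int
    ref: str
    alt: str
    block_id: str | None = None
    in_tandem_repeat: bool = False
    variant_id: str = ""

    def __post_init__(self):
        if self.kind == "snv":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError("snv must be a single differing base")
        elif self.kind == "deletion":
            if not (1 <= len(self.ref) <= MAX_INDEL) or self.alt:
                raise ValueError("deletion length outside [1, 90]")
        elif self.kind == "insertion":
            if not (1 <= len(self.alt) <= MAX_INDEL) or self.ref:
                raise ValueError("insertion length outside [1, 90]")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")

    @property
    def length(self) -> int:
        return max(len(self.ref), len(self.alt)) if self.kind != "snv" else 1

    @property
    def interval(self) -> GenomicInterval:
        end = self.pos + (len(self.ref) if self.kind != "insertion" else 0)
        return GenomicInterval(self.seq_id, self.pos, max(end, self.pos))


@dataclass(frozen=True)
class StructuralEvent:
    """A gap run too long for the small-indel caller (kept for QC stages)."""

    kind: str  # insertion | deletion
    seq_id: str
    ref_start: int
    length: int
    block_id: str


@dataclass(frozen=True)
class TandemRepeatLocus:
    interval: GenomicInterval
    unit: int
    copies: float


@dataclass(frozen=True)
class VariantAnnotation:
    variant_id: str
    gene_id: str | None
    effect: str  # sense | missense | inframe_indel | frameshift | start_stop_altered | intergenic
    frame_preserved: bool


# ---------------------------------------------------------------------------
# Calling


def _left_normalize(seq: str, pos: int, allele: str) -> tuple[int, str]:
    """Shift an indel allele left through its repeat context (VCF style)."""
    while pos > 0 and allele and seq[pos - 1] == allele[-1]:
        allele = seq[pos - 1] + allele[:-1]
        pos -= 1
    return pos, allele


def call_variants(
    blocks: list[AlignmentBlock],
    query_seqs: dict[str, str],
    ref_seqs: dict[str, str],
    min_identity: float = 0.97,
    max_indel: int = MAX_INDEL,
    structural_out: list | None = None,
) -> list[VariantCall]:
    """Call SNVs and indels from non-ambiguous, high-identity blocks.

    Gap runs longer than ``max_indel`` are appended to ``structural_out``
    (if given) and logged, never emitted as indels. The identity filter is
    applied per contiguous aligned segment (blocks are split at structural
    gaps first), so one large planted deletion does not disqualify an
    otherwise near-identical alignment.
    """
    for b in blocks:
        if b.ref_id not in ref_seqs:
            raise KeyError(f"block {b.block_id} references unknown sequence {b.ref_id}")
        if b.ambiguous:
            continue
        for op, rs, _q, n in b.gaps(min_len=max_indel + 1):
            _log_structural(
                structural_out, "deletion" if op == "D" else "insertion", b, rs, n
            )
    calls: dict[tuple, VariantCall] = {}
    for b in split_blocks_at_large_gaps(blocks, min_gap=max_indel + 1):
        if b.ambiguous or b.identity < min_identity:
            continue
        rseq = ref_seqs[b.ref_id]
        qsub = query_seqs[b.query_id][b.q_start : b.q_end]
        if b.strand == "-":
            qsub = revcomp(qsub)
        for op, n, q, r in b.walk():
            rpos = b.r_start + r
            if op == "X":
                for t in range(n):
                    key = ("snv", b.ref_id, rpos + t)
                    calls.setdefault(
                        key,
                        VariantCall(
                            "snv", b.ref_id, rpos + t,
                            rseq[rpos + t], qsub[q + t], b.block_id,
                        ),
                    )
            elif op == "D":
                if n > max_indel:  # unreachable after splitting; belt-and-braces
                    continue
                pos, allele = _left_normalize(rseq, rpos, rseq[rpos : rpos + n])
                calls.setdefault(
                    ("del", b.ref_id, pos, allele),
                    VariantCall("deletion", b.ref_id, pos, allele, "", b.block_id),
                )
            elif op == "I":
                if n > max_indel:
                    continue
                pos, allele = _left_normalize(rseq, rpos, qsub[q : q + n])
                calls.setdefault(
                    ("ins", b.ref_id, pos, allele),
                    VariantCall("insertion", b.ref_id, pos, "", allele, b.block_id),
                )
    out = sorted(calls.values(), key=lambda c: (c.seq_id, c.pos, c.kind, c.alt, c.ref))
    for i, c in enumerate(out):
        c.variant_id = f"var{i+1:06d}"
    return out


def _log_structural(structural_out, kind, block, rpos, n):
    logger.info(
        "structural %s of %d bp at %s:%d (block %s) exceeds small-indel limit",
        kind, n, block.ref_id, rpos, block.block_id,
    )
    if structural_out is not None:
        structural_out.append(StructuralEvent(kind, block.ref_id, rpos, n, block.block_id))


# ---------------------------------------------------------------------------
# Tandem repeats


def detect_tandem_repeats(
    records, max_unit: int = 60, min_span_units: int = 2, min_span_bp: int = 0
) -> list[TandemRepeatLocus]:
    """All maximal perfect tandem arrays with unit <= max_unit and at least
    ``min_span_units`` copies; overlapping reports merged by longest span.

    ``min_span_bp`` additionally drops arrays shorter than that many bases —
    at genome scale the 2-copy micro-arrays (every duplicated dinucleotide)
    are ubiquitous noise, so pipelines pass e.g. 8."""
    if not isinstance(records, list):
        records = [records]
    cands: dict[tuple[str, int, int], int] = {}
    for rec in records:
        arr = np.frombuffer(rec.seq.encode(), dtype=np.uint8)
        n = len(arr)
        for u in range(1, min(max_unit, n - 1) + 1):
            eq = arr[u:] == arr[:-u]
            if not eq.any():
                continue
            padded = np.concatenate(([False], eq, [False]))
            d = np.diff(padded.astype(np.int8))
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1)
            runs = ends - starts
            keep = (runs >= u * (min_span_units - 1)) & (runs + u >= min_span_bp)
            for s, run in zip(starts[keep], runs[keep]):
                key = (rec.id, int(s), int(s + run + u))
                if key not in cands or u < cands[key]:
                    cands[key] = u
    loci = [
        TandemRepeatLocus(GenomicInterval(sid, s, e), u, (e - s) / u)
        for (sid, s, e), u in cands.items()
    ]
    loci.sort(key=lambda t: (-(t.interval.end - t.interval.start), t.interval.seq_id,
                             t.interval.start, t.unit))
    kept: list[TandemRepeatLocus] = []
    occupied: dict[str, IntervalTree] = {}
    for t in loci:
        tree = occupied.setdefault(t.interval.seq_id, IntervalTree())
        if not tree.overlap(t.interval.start, t.interval.end):
            kept.append(t)
            tree.addi(t.interval.start, t.interval.end)
    kept.sort(key=lambda t: (t.interval.seq_id, t.interval.start))
    return kept


# ---------------------------------------------------------------------------
# Annotation


def _codon_change(gene: GeneModel, cds: str, cds_pos: int, alt_base: str):
    """Reference and mutated codon at a CDS offset (alt already CDS-strand)."""
    ci = cds_pos // 3
    codon = cds[3 * ci : 3 * ci + 3]
    mut = codon[: cds_pos % 3] + alt_base + codon[cds_pos % 3 + 1 :]
    return ci, codon, mut


def annotate_variants(
    calls: list[VariantCall],
    genes: list[GeneModel],
    repeats: list[TandemRepeatLocus],
    ref_seqs: dict[str, str],
    codon_table: int = 1,
) -> list[VariantAnnotation]:
    """Classify each call's gene effect and set its tandem-repeat flag.

    SNVs in CDS are sense (synonymous) or missense by codon translation on
    the coding strand; in-CDS indels are frameshift iff length % 3 != 0;
    edits touching the first or last codon are start_stop_altered. Genes
    whose CDS length is not a multiple of 3 are skipped with a warning.
    """
    rep_by_chrom: dict[str, list[TandemRepeatLocus]] = {}
    for r in repeats or []:
        rep_by_chrom.setdefault(r.interval.seq_id, []).append(r)
    out: list[VariantAnnotation] = []
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.interval.seq_id, []).append(g)
    warned: set[str] = set()
    for c in calls:
        c.in_tandem_repeat = any(
            c.interval.overlaps(r.interval) or
            (c.kind == "insertion" and r.interval.start < c.pos < r.interval.end)
            for r in rep_by_chrom.get(c.seq_id, [])
        )
        gene = None
        for g in genes_by_chrom.get(c.seq_id, []):
            hit = (
                c.interval.overlaps(g.interval)
                if c.kind != "insertion"
                else g.interval.start < c.pos < g.interval.end
            )
            if hit:
                gene = g
                break
        if gene is None:
            out.append(VariantAnnotation(c.variant_id, None, "intergenic", True))
            continue
        if gene.cds_length % 3 != 0:
            if gene.gene_id not in warned:
                logger.warning("gene %s CDS length not divisible by 3; skipped", gene.gene_id)
                warned.add(gene.gene_id)
            continue
        n_codons = gene.cds_length // 3
        iv = gene.cds_intervals[0]  # single-CDS models
        cds = gene.cds_sequence(ref_seqs)
        if c.kind == "snv":
            if gene.strand == "+":
                cds_pos = c.pos - iv.start
                alt = c.alt
            else:
                cds_pos = iv.end - 1 - c.pos
                alt = revcomp(c.alt)
            ci, codon, mut = _codon_change(gene, cds, cds_pos, alt)
            aa_ref = str(Seq(codon).translate(table=codon_table))
            aa_alt = str(Seq(mut).translate(table=codon_table))
            if aa_ref == aa_alt:
                effect = "sense"
            elif ci == 0 and mut != "ATG":
                effect = "start_stop_altered"
            elif ci == n_codons - 1 and aa_alt != "*":
                effect = "start_stop_altered"
            else:
                effect = "missense"
            out.append(
                VariantAnnotation(c.variant_id, gene.gene_id, effect,
                                  effect != "start_stop_altered")
            )
        else:
            frameshift = c.length % 3 != 0
            if gene.strand == "+":
                first = GenomicInterval(c.seq_id, iv.start, iv.start + 3)
                last = GenomicInterval(c.seq_id, iv.end - 3, iv.end)
            else:
                first = GenomicInterval(c.seq_id, iv.end - 3, iv.end)
                last = GenomicInterval(c.seq_id, iv.start, iv.start + 3)
            touches_ends = c.interval.overlaps(first) or c.interval.overlaps(last)
            if c.kind == "insertion":
                touches_ends = (
                    first.start < c.pos < first.end or last.start < c.pos < last.end
                )
            if touches_ends:
                effect = "start_stop_altered"
            elif frameshift:
                effect = "frameshift"
            else:
                effect = "inframe_indel"
            out.append(
                VariantAnnotation(
                    c.variant_id, gene.gene_id, effect,
                    not frameshift and effect != "start_stop_altered",
                )
            )
    return out
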