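"""Contig tiling on the reference, gap causes, and transposon locus states.

Every contig is assigned its best location on the reference (aligned
length x identity). Reference regions between consecutive placements are
*gaps*; a gap containing at least one base covered by no read is labeled
``missing_sequence`` (data absent), a gap overlapping a >95%-self-identity
repeat is ``unassembled`` (data present, assembly failed), ``both`` when
both hold and ``unexplained`` otherwise.

At each annotated transposon locus three situations are distinguished:
the element is absent and a single contig spans the locus with a deletion
gap of roughly the element length (GA, absent_gapped); the element is
present but unassembled so two contigs terminate at its flanks (CB,
present_break); or a gapless alignment crosses the locus (AS,
present_assembled). Precedence AS > GA > CB; loci matching no pattern are
conservatively labeled present_break with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .align import AlignmentBlock, RepeatRegion
from .io import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class ContigPlacement:
    contig_id: str
    interval: GenomicInterval  # chosen reference interval
    strand: str
    score: float  # aligned length x identity
    order_index: int = -1


@dataclass
class GapCall:
    interval: GenomicInterval  # reference interval between placements
    has_zero_coverage_base: bool
    overlaps_repeat: bool
    label: str  # missing_sequence | unassembled | both | unexplained


@dataclass
class TransposonCall:
    locus_id: str
    family: str
    label: str  # absent_gapped | present_break | present_assembled
    gap_size: int | None = None  # only for absent_gapped


def tile_contigs(blocks: list[AlignmentBlock], min_identity: float = 0.0):
    """Best placement per contig; ties broken toward the lower reference
    coordinate. Returns (placements sorted along the reference, unplaced ids)."""
    best: dict[str, AlignmentBlock] = {}
    seen: set[str] = set()
    for b in blocks:
        seen.add(b.query_id)
        if b.identity < min_identity:
            continue
        cur = best.get(b.query_id)
        if (
            cur is None
            or b.score > cur.score
            or (b.score == cur.score and (b.ref_id, b.r_start) < (cur.ref_id, cur.r_start))
        ):
            if cur is not None and b.score == cur.score:
                logger.info(
                    "contig %s places equally at %s:%d and %s:%d; keeping lower",
                    b.query_id, cur.ref_id, cur.r_start, b.ref_id, b.r_start,
                )
            best[b.query_id] = b
    placements = [
        ContigPlacement(qid, b.ref_interval, b.strand, b.score)
        for qid, b in best.items()
    ]
    placements.sort(key=lambda p: (p.interval.seq_id, p.interval.start, p.contig_id))
    for i, p in enumerate(placements):
        p.order_index = i
    unplaced = sorted(seen - set(best))
    return placements, unplaced


def classify_gaps(
    placements: list[ContigPlacement],
    depth: dict[str, np.ndarray],
    repeats: list[RepeatRegion],
) -> list[GapCall]:
    """Label the reference regions between consecutive contig placements.

    ``depth`` is per-base read coverage of the query strain on the
    reference."""
    rep_iv: dict[str, list[tuple[int, int]]] = {}
    for r in repeats:
        rep_iv.setdefault(r.interval.seq_id, []).append((r.interval.start, r.interval.end))
    out: list[GapCall] = []
    by_chrom: dict[str, list[ContigPlacement]] = {}
    for p in placements:
        by_chrom.setdefault(p.interval.seq_id, []).append(p)
    for chrom, ps in by_chrom.items():
        ps.sort(key=lambda p: p.interval.start)
        cursor = ps[0].interval.end
        for p in ps[1:]:
            s, e = cursor, p.interval.start
            cursor = max(cursor, p.interval.end)
            if e <= s:
                continue
            zero = bool((np.asarray(depth[chrom][s:e]) == 0).any())
            rep = any(rs < e and s < re_ for rs, re_ in rep_iv.get(chrom, []))
            if zero and rep:
                label = "both"
            elif zero:
                label = "missing_sequence"
            elif rep:
                label = "unassembled"
            else:
                label = "unexplained"
            out.append(GapCall(GenomicInterval(chrom, s, e), zero, rep, label))
    return out


def gap_totals(gaps: list[GapCall]) -> dict[str, int]:
    """Total gap length per label (the headline summary of the gap analysis)."""
    tot: dict[str, int] = {}
    for g in gaps:
        tot[g.label] = tot.get(g.label, 0) + len(g.interval)
    return tot


def classify_transposons(
    loci,
    placements: list[ContigPlacement],
    blocks: list[AlignmentBlock],
    element_length_tolerance: float = 0.2,
    flank_window: int = 1000,
    min_gap: int = 100,
) -> list[TransposonCall]:
    """GA/CB/AS state of each annotated transposon locus (see module docs)."""
    out: list[TransposonCall] = []
    by_ref: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_ref.setdefault(b.ref_id, []).append(b)
    for locus in loci:
        iv = locus.interval
        cands = by_ref.get(iv.seq_id, [])
        spanning = [
            b for b in cands if b.r_start < iv.start and b.r_end > iv.end
        ]
        label, gap = None, None
        elen = len(iv)
        # AS: a spanning block with no sizeable gap over the locus
        for b in spanning:
            gaps_here = [
                g for g in b.gaps(min_len=min_gap)
                if g[1] < iv.end and g[1] + (g[3] if g[0] == "D" else 0) > iv.start
            ]
            if not gaps_here:
                label = "present_assembled"
                break
        if label is None:
            # GA: spanning block with a query-side deletion of ~element length
            for b in spanning:
                for op, rs, _q, n in b.gaps(min_len=min_gap):
                    if op != "D":
                        continue
                    if rs < iv.end and rs + n > iv.start and abs(n - elen) <= element_length_tolerance * elen:
                        label, gap = "absent_gapped", n
                        break
                if label:
                    break
        if label is None:
            # CB: distinct contigs terminating at either flank
            left = {
                b.query_id
                for b in cands
                if abs(b.r_end - iv.start) <= flank_window and b.r_start < iv.start
            }
            right = {
                b.query_id
                for b in cands
                if abs(b.r_start - iv.end) <= flank_window and b.r_end > iv.end
            }
            if left and right and (left | right) - (left & right):
                label = "present_break"
        if label is None:
            logger.warning(
                "transposon locus %s matches no GA/CB/AS pattern; labeling present_break",
                locus.locus_id,
            )
            label = "present_break"
        out.append(TransposonCall(locus.locus_id, locus.family, label, gap))
    return out


def ty_family_copy_estimate(
    loci,
    depth_test: dict[str, np.ndarray],
    depth_ref: dict[str, np.ndarray],
    norm_window: int = 1000,
) -> dict[str, dict]:
    """Per-family copy-number estimate in the test strain from the depth
    ratio over each annotated element.

    estimate = reference family count x median per-element depth ratio,
    rounded to the nearest integer. Ratios are normalized by the
    genome-wide median window ratio (robust to CNVs and to genome-size
    differences between the strains), so rescaling either track leaves the
    estimate unchanged. The median is taken on the linear ratio scale,
    which equals 2^(median log2 ratio) for odd counts and stays defined
    when excised elements drive ratios to 0.
    """
    total_test = sum(float(np.sum(v)) for v in depth_test.values())
    total_ref = sum(float(np.sum(v)) for v in depth_ref.values())
    wx, wy = [], []
    for chrom in depth_test:
        n = len(depth_test[chrom]) // norm_window * norm_window
        if n == 0:
            continue
        wx.append(np.asarray(depth_test[chrom][:n]).reshape(-1, norm_window).sum(axis=1))
        wy.append(np.asarray(depth_ref[chrom][:n]).reshape(-1, norm_window).sum(axis=1))
    wx, wy = np.concatenate(wx), np.concatenate(wy)
    ok = wy > 0
    baseline = float(np.median((wx[ok] / total_test) / (wy[ok] / total_ref)))
    fam: dict[str, list[tuple[str, float]]] = {}
    for locus in loci:
        iv = locus.interval
        x = float(np.sum(depth_test[iv.seq_id][iv.start : iv.end]))
        y = float(np.sum(depth_ref[iv.seq_id][iv.start : iv.end]))
        if y == 0:
            logger.warning("locus %s has zero reference depth; skipped", locus.locus_id)
            continue
        ratio = (x / total_test) / (y / total_ref) / baseline
        fam.setdefault(locus.family, []).append((locus.locus_id, ratio))
    out: dict[str, dict] = {}
    for family, pairs in fam.items():
        ratios = np.array([r for _, r in pairs])
        out[family] = {
            "reference_count": len(pairs),
            "estimate": int(round(len(pairs) * float(np.median(ratios)))),
            "per_element_ratio": dict(pairs),
        }
    return out
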