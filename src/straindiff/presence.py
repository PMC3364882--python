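"""Gene presence/absence, high-confidence deletions, and query-unique regions.

A reference gene is *present* when some alignment block covers at least
80% of it at >= 95% identity. Genes missing from the assembly alone may be
assembly dropouts (e.g. at repeats), so a gene is only a
*high-confidence deletion* when it is both absent from the assembly and
depleted in read depth (mean log2 depth ratio < -0.6): the intersection
of the two evidence sets.

A query region is *unique* when it shows <95% identity to any reference
region after keeping, for each reference position, only the best-aligned
query region — so the extra copies of query-side duplications also
surface as unique. Unique regions can be screened against a panel of
other strain genomes, keeping hits with query coverage > 60% and
identity > 90%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import (
    AlignmentBlock,
    AlignParams,
    KmerIndex,
    chain_and_extend,
    scan_mems,
    split_blocks_at_large_gaps,
)
from .io import GenomicInterval, GeneModel, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class PresenceCall:
    gene_id: str
    best_identity: float | None
    mean_log2: float
    status: str  # present | absent_in_assembly | low_depth | deleted_high_confidence


@dataclass
class ConservationHit:
    strain_id: str
    coverage: float
    identity: float


@dataclass
class UniqueRegion:
    interval: GenomicInterval  # query coordinates
    best_kept_identity: float | None  # identity of kept alignments over the region
    genes: tuple = ()
    conservation: list = field(default_factory=list)


def gene_presence(
    genes: list[GeneModel],
    blocks: list[AlignmentBlock],
    gene_log2: dict[str, float],
    min_identity: float = 0.95,
    depth_cut: float = -0.6,
    min_coverage: float = 0.8,
) -> list[PresenceCall]:
    """Classify each reference gene's presence in the query assembly.

    ``gene_log2`` maps gene_id to the mean log2 depth ratio over the gene
    (see :func:`mean_log2_per_gene`)."""
    by_ref: dict[str, list[AlignmentBlock]] = {}
    for b in split_blocks_at_large_gaps(blocks):
        by_ref.setdefault(b.ref_id, []).append(b)
    out = []
    for g in genes:
        iv = g.interval
        best = None
        for b in by_ref.get(iv.seq_id, []):
            ov = b.ref_interval.overlap_len(iv)
            if ov >= min_coverage * len(iv):
                best = b.identity if best is None else max(best, b.identity)
        lg = gene_log2.get(g.gene_id, 0.0)
        assembled = best is not None and best >= min_identity
        low = lg < depth_cut
        if assembled:
            status = "low_depth" if low else "present"
        else:
            status = "deleted_high_confidence" if low else "absent_in_assembly"
        out.append(PresenceCall(g.gene_id, best, lg, status))
    return out


def mean_log2_per_gene(genes: list[GeneModel], windows) -> dict[str, float]:
    """Mean window log2 depth ratio over each gene's interval."""
    out: dict[str, float] = {}
    for g in genes:
        vals = [
            w.log2_ratio for w in windows if w.interval.overlaps(g.interval)
        ]
        out[g.gene_id] = float(np.mean(vals)) if vals else 0.0
    return out


# ---------------------------------------------------------------------------
# Unique regions


def unique_regions(
    query_records: list[SequenceRecord],
    ref_records: list[SequenceRecord],
    blocks: list[AlignmentBlock],
    min_identity: float = 0.95,
    min_length: int = 500,
    genes_by_query=None,
) -> list[UniqueRegion]:
    """Query regions with <min_identity to any reference region after
    best-alignment-per-reference-position filtering.

    Blocks at >= min_identity are visited best-first; each claims the
    reference positions not already claimed by a better block, and only the
    query positions projected from newly claimed reference stretches count
    as explained. Unexplained query runs >= min_length are unique.
    """
    claimed = {r.id: np.zeros(len(r.seq), dtype=bool) for r in ref_records}
    covered = {q.id: np.zeros(len(q.seq), dtype=bool) for q in query_records}
    kept_identity = {q.id: np.zeros(len(q.seq)) for q in query_records}
    parent_len = {b.block_id: b.aligned_length for b in blocks}
    segments = split_blocks_at_large_gaps(blocks)
    # claim order: segments of longer parent chains first (collinear primary
    # alignments), then identity -- so the extra copy of a duplication, not
    # the collinear original, is left unexplained and surfaces as unique
    order = sorted(
        (b for b in segments if b.identity >= min_identity),
        key=lambda b: (
            -parent_len.get(b.block_id.split(".")[0], b.aligned_length),
            -b.identity,
            b.query_id,
            b.q_start,
        ),
    )
    for b in order:
        ref_mask = claimed[b.ref_id][b.r_start : b.r_end]
        free = ~ref_mask
        if not free.any():
            continue
        # project each newly claimed reference stretch onto the query
        d = np.diff(np.concatenate(([0], free.astype(np.int8), [0])))
        for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
            qs, qe = b.ref_to_query(b.r_start + int(s), b.r_start + int(e))
            covered[b.query_id][qs:qe] = True
            sl = kept_identity[b.query_id][qs:qe]
            np.maximum(sl, b.identity, out=sl)
        claimed[b.ref_id][b.r_start : b.r_end] = True
    out: list[UniqueRegion] = []
    for q in query_records:
        un = ~covered[q.id]
        d = np.diff(np.concatenate(([0], un.astype(np.int8), [0])))
        for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
            if e - s < min_length:
                continue
            iv = GenomicInterval(q.id, int(s), int(e))
            genes = tuple(
                g.gene_id for g in (genes_by_query or []) if g.interval.overlaps(iv)
            )
            out.append(UniqueRegion(iv, None, genes))
    return out


def conservation_screen(
    regions: list[UniqueRegion],
    query_records: list[SequenceRecord],
    panel: dict[str, list[SequenceRecord]],
    min_coverage: float = 0.60,
    min_identity: float = 0.90,
    params: AlignParams | None = None,
) -> list[UniqueRegion]:
    """Annotate each unique region with the panel strains that conserve it.

    For each strain the best local alignment of the region is found; hits
    are kept when query coverage > min_coverage AND identity > min_identity
    (both strict). Hits are sorted by coverage x identity."""
    if not panel:
        raise ValueError("conservation screen requires a non-empty panel")
    params = params or AlignParams(min_mem=15, min_chain_score=40)
    qseqs = {q.id: q.seq for q in query_records}
    indexes = {sid: KmerIndex(recs, params.min_mem) for sid, recs in panel.items()}
    for region in regions:
        iv = region.interval
        frag = SequenceRecord(f"{iv.seq_id}:{iv.start}-{iv.end}", qseqs[iv.seq_id][iv.start : iv.end])
        hits = []
        for sid, idx in indexes.items():
            mems = scan_mems(frag.seq, frag.id, idx, params.min_mem, "+")
            bls = chain_and_extend(mems, frag, idx.refs, params)
            if not bls:
                continue
            best = max(bls, key=lambda b: b.score)
            cov = best.aligned_length / len(frag.seq)
            if cov > min_coverage and best.identity > min_identity:
                hits.append(ConservationHit(sid, cov, best.identity))
        hits.sort(key=lambda h: -h.coverage * h.identity)
        region.conservation = hits
    return regions
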