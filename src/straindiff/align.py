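"""Anchor-based whole-genome alignment and self-alignment repeat detection.

The aligner follows the classical seed-chain-extend design used for
assembly-to-reference comparison:

1. *Seeding*: maximal exact matches (MEMs) of length >= ``min_mem`` are
   enumerated with a k-mer index, extended to maximality, and deduplicated
   per diagonal.
2. *Chaining*: collinear, same-strand anchors are chained with an affine
   gap cost; the chain with the highest anchored coverage is extracted,
   its anchors retired, and the process repeats so that secondary
   alignments of repeated sequence (needed for ambiguity flagging) are
   also reported.
3. *Polishing*: the edit path over each chained region is recomputed as an
   optimal unit-cost global alignment (edlib), so a block's edit distance
   equals the full dynamic-programming optimum over its aligned region.

Identity is matches / aligned columns, recomputable from the edit path.
``N`` never matches any base, including another ``N``.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from .io import GenomicInterval, SequenceRecord, revcomp

logger = logging.getLogger(__name__)

_CIG_RE = re.compile(r"(\d+)([=XID])")


@dataclass(frozen=True)
class ExactMatch:
    """A maximal exact match. For strand '-',
    revcomp(query[q_start:q_end]) == reference[r_start:r_end]."""

    query_id: str
    q_start: int
    q_end: int
    ref_id: str
    r_start: int
    r_end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


@dataclass
class AlignmentBlock:
    """A gapped alignment between a query interval and a reference interval.

    ``cigar`` is a list of (op, length) runs over {'=', 'X', 'I', 'D'} where
    'I' consumes query only and 'D' consumes reference only. For strand '-'
    the cigar walks the reverse-complemented query against the forward
    reference; q_start/q_end are always forward-strand query coordinates.
    """

    query_id: str
    q_start: int
    q_end: int
    ref_id: str
    r_start: int
    r_end: int
    strand: str
    cigar: list[tuple[str, int]]
    identity: float
    ambiguous: bool = False
    block_id: str = ""
    edit_distance: int = -1  # optimal unit-cost distance over the aligned region

    def __post_init__(self):
        qlen = sum(n for op, n in self.cigar if op in "=XI")
        rlen = sum(n for op, n in self.cigar if op in "=XD")
        if qlen != self.q_end - self.q_start or rlen != self.r_end - self.r_start:
            raise ValueError(
                f"cigar lengths ({qlen},{rlen}) do not match intervals of {self.block_id}"
            )

    @property
    def n_match(self) -> int:
        return sum(n for op, n in self.cigar if op == "=")

    @property
    def n_columns(self) -> int:
        return sum(n for _, n in self.cigar)

    @property
    def query_interval(self) -> GenomicInterval:
        return GenomicInterval(self.query_id, self.q_start, self.q_end, self.strand)

    @property
    def ref_interval(self) -> GenomicInterval:
        return GenomicInterval(self.ref_id, self.r_start, self.r_end, "+")

    @property
    def aligned_length(self) -> int:
        return self.q_end - self.q_start

    @property
    def score(self) -> float:
        """Placement score: aligned length x identity."""
        return self.aligned_length * self.identity

    def recompute_identity(self) -> float:
        cols = self.n_columns
        return self.n_match / cols if cols else 0.0

    # -- coordinate walking helpers ------------------------------------

    def walk(self):
        """Yield (op, length, q_off, r_off) with offsets into the aligned
        regions (q offsets along the cigar orientation)."""
        q = r = 0
        for op, n in self.cigar:
            yield op, n, q, r
            if op in "=XI":
                q += n
            if op in "=XD":
                r += n

    def gaps(self, min_len: int = 1):
        """Deletion/insertion runs >= min_len as (op, ref_start, q_off, length)."""
        out = []
        for op, n, q, r in self.walk():
            if op in "ID" and n >= min_len:
                out.append((op, self.r_start + r, q, n))
        return out

    def ref_to_query(self, rs: int, re_: int) -> tuple[int, int]:
        """Project a reference sub-interval onto forward query coordinates
        (approximate at gap edges)."""
        rs = max(rs, self.r_start)
        re_ = min(re_, self.r_end)
        qa = qb = None
        for op, n, q, r in self.walk():
            r0, r1 = self.r_start + r, self.r_start + r + (n if op in "=XD" else 0)
            if op in "=X":
                if qa is None and r1 > rs:
                    qa = q + max(0, rs - r0)
                if r1 >= re_ and qb is None:
                    qb = q + max(0, re_ - r0)
                    break
            elif op == "D":
                if qa is None and r1 > rs:
                    qa = q
                if r1 >= re_ and qb is None:
                    qb = q
                    break
        if qa is None:
            qa = 0
        if qb is None:
            qb = self.aligned_length
        if self.strand == "+":
            return self.q_start + qa, self.q_start + qb
        return self.q_end - qb, self.q_end - qa


@dataclass(frozen=True)
class RepeatRegion:
    """A genomic region with a >95%-identity partner elsewhere in the genome."""

    interval: GenomicInterval
    partner: GenomicInterval
    identity: float


@dataclass
class AlignParams:
    """Tunable aligner parameters (defaults suit yeast-scale genomes)."""

    min_mem: int = 20
    both_strands: bool = False
    max_join_gap: int = 1000       # max gap on the smaller side of a join
    max_join_sv: int = 20000       # max gap on the larger side (spans SVs)
    min_chain_score: float = 60.0  # stop extracting chains below this
    max_chains: int = 400          # per (ref, strand) group
    lookback: int = 60             # chaining predecessor window
    gap_open: float = 20.0
    gap_ext: float = 0.05
    extend_to_query_ends: bool = False
    refine_gaps: bool = True


# ---------------------------------------------------------------------------
# Seeding


class KmerIndex:
    """Exact k-mer index over a set of reference sequences."""

    def __init__(self, refs: list[SequenceRecord], k: int):
        self.k = k
        self.refs = refs
        self.seqs = {r.id: r.seq for r in refs}
        index: dict[str, list[tuple[int, int]]] = {}
        for ri, rec in enumerate(refs):
            s = rec.seq
            for j in range(len(s) - k + 1):
                kmer = s[j : j + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((ri, j))
        self.index = index

    def hits(self, kmer: str):
        return self.index.get(kmer, ())


def _extend_right(a: str, b: str, i: int, j: int, chunk: int = 128) -> int:
    """Length of the exact match run starting at a[i], b[j] (N never matches)."""
    n = 0
    la, lb = len(a), len(b)
    while True:
        c = min(chunk, la - (i + n), lb - (j + n))
        if c <= 0:
            return n
        ca, cb = a[i + n : i + n + c], b[j + n : j + n + c]
        if ca == cb and "N" not in ca:
            n += c
            continue
        for t in range(c):
            x = ca[t]
            if x != cb[t] or x == "N":
                return n + t
        n += c  # unreachable guard


def _extend_left(a: str, b: str, i: int, j: int, chunk: int = 128) -> int:
    n = 0
    while True:
        c = min(chunk, i - n, j - n)
        if c <= 0:
            return n
        ca, cb = a[i - n - c : i - n], b[j - n - c : j - n]
        if ca == cb and "N" not in ca:
            n += c
            continue
        for t in range(1, c + 1):
            x = ca[-t]
            if x != cb[-t] or x == "N":
                return n + t - 1
        n += c


def scan_mems(
    qseq: str,
    query_id: str,
    index: KmerIndex,
    min_length: int,
    strand: str = "+",
    skip_trivial_diag: str | None = None,
) -> list[ExactMatch]:
    """Enumerate MEMs of ``qseq`` (already oriented) against the index.

    ``skip_trivial_diag``: reference id whose zero-offset diagonal is the
    trivial self-match to exclude (self-alignment mode).
    """
    k = index.k
    qlen = len(qseq)
    seen: dict[tuple[int, int], int] = {}
    out: list[ExactMatch] = []
    refs = index.refs
    hits = index.hits
    for i in range(qlen - k + 1):
        hh = hits(qseq[i : i + k])
        if not hh:
            continue
        for ri, j in hh:
            if skip_trivial_diag is not None and refs[ri].id == skip_trivial_diag and j == i:
                continue
            key = (ri, j - i)
            if seen.get(key, -1) > i:
                continue
            rseq = refs[ri].seq
            left = _extend_left(qseq, rseq, i, j)
            right = _extend_right(qseq, rseq, i, j)
            qs, qe = i - left, i + right
            seen[key] = qe
            if qe - qs >= min_length:
                rs = j - left
                if strand == "+":
                    out.append(
                        ExactMatch(query_id, qs, qe, refs[ri].id, rs, rs + (qe - qs), "+")
                    )
                else:
                    out.append(
                        ExactMatch(
                            query_id, qlen - qe, qlen - qs,
                            refs[ri].id, rs, rs + (qe - qs), "-",
                        )
                    )
    out.sort(key=lambda m: (m.ref_id, m.r_start, m.q_start))
    return out


def find_mems(
    query: SequenceRecord,
    reference: SequenceRecord,
    min_length: int = 20,
    both_strands: bool = False,
) -> list[ExactMatch]:
    """All maximal exact matches of length >= min_length between two sequences,
    sorted by reference position."""
    if min_length < 10:
        raise ValueError("min_length must be >= 10")
    if not query.seq or not reference.seq:
        return []
    index = KmerIndex([reference], min(min_length, len(reference.seq)))
    if index.k > len(reference.seq):
        return []
    out = scan_mems(query.seq, query.id, index, min_length, "+")
    if both_strands:
        out += scan_mems(revcomp(query.seq), query.id, index, min_length, "-")
    out.sort(key=lambda m: (m.ref_id, m.r_start, m.q_start, m.strand))
    return out


# ---------------------------------------------------------------------------
# Chaining and extension


def parse_cigar(cig: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIG_RE.findall(cig)]


def _edlib_path(qseq: str, rseq: str) -> list[tuple[str, int]]:
    """Optimal unit-cost global edit path; N never matches."""
    if not qseq and not rseq:
        return []
    if not qseq:
        return [("D", len(rseq))]
    if not rseq:
        return [("I", len(qseq))]
    res = edlib.align(qseq.replace("N", "n"), rseq, task="path", mode="NW")
    return parse_cigar(res["cigar"])


_aligner = None


def _affine_aligner():
    """Affine-gap global aligner used to consolidate gap placement in small
    windows (unit-cost optima are non-unique and can scatter an indel)."""
    global _aligner
    if _aligner is None:
        from Bio import Align

        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = -1.5
        a.open_gap_score = -3.0
        a.extend_gap_score = -0.5
        _aligner = a
    return _aligner


def _affine_path(qseq: str, rseq: str) -> list[tuple[str, int]]:
    """Affine-gap global edit path (query vs reference) from biopython."""
    if not qseq:
        return [("D", len(rseq))] if rseq else []
    if not rseq:
        return [("I", len(qseq))]
    aln = _affine_aligner().align(rseq.replace("N", "n"), qseq)[0]
    coords = aln.coordinates  # row 0: reference, row 1: query
    ops: list[tuple[str, int]] = []

    def push(op, n):
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    for c in range(coords.shape[1] - 1):
        r0, r1 = int(coords[0, c]), int(coords[0, c + 1])
        q0, q1 = int(coords[1, c]), int(coords[1, c + 1])
        if r1 > r0 and q1 > q0:
            for t in range(r1 - r0):
                if rseq[r0 + t] == qseq[q0 + t] and rseq[r0 + t] != "N":
                    push("=", 1)
                else:
                    push("X", 1)
        elif r1 > r0:
            push("D", r1 - r0)
        elif q1 > q0:
            push("I", q1 - q0)
    return ops


def _expand(cigar: list[tuple[str, int]]):
    for op, n in cigar:
        for _ in range(n):
            yield op


def refine_cigar(
    qseq: str, rseq: str, cigar: list[tuple[str, int]],
    pad: int = 25, merge_window: int = 30, max_segment: int = 30000,
) -> list[tuple[str, int]]:
    """Re-align gap-containing neighborhoods of an edit path with affine
    gap costs, consolidating indel runs that a unit-cost path may scatter.

    Neighborhoods are maximal clusters of I/D columns closer than
    ``merge_window``, padded by ``pad`` matched columns on each side.
    """
    cols = list(_expand(cigar))
    gap_idx = [i for i, op in enumerate(cols) if op in "ID"]
    if not gap_idx:
        return cigar
    # cluster gap columns
    segments: list[tuple[int, int]] = []
    s = e = gap_idx[0]
    for i in gap_idx[1:]:
        if i - e <= merge_window:
            e = i
        else:
            segments.append((s, e + 1))
            s = e = i
    segments.append((s, e + 1))
    # pad and merge overlapping padded segments
    padded = []
    for s, e in segments:
        s, e = max(0, s - pad), min(len(cols), e + pad)
        if padded and s <= padded[-1][1]:
            padded[-1] = (padded[-1][0], e)
        else:
            padded.append((s, e))
    # column -> (q, r) offsets
    qoff = np.zeros(len(cols) + 1, dtype=np.int64)
    roff = np.zeros(len(cols) + 1, dtype=np.int64)
    for i, op in enumerate(cols):
        qoff[i + 1] = qoff[i] + (op in "=XI")
        roff[i + 1] = roff[i] + (op in "=XD")
    new_cols: list[str] = []
    prev = 0
    for s, e in padded:
        new_cols.extend(cols[prev:s])
        q0, q1 = qoff[s], qoff[e]
        r0, r1 = roff[s], roff[e]
        if (q1 - q0) + (r1 - r0) > max_segment:
            new_cols.extend(cols[s:e])  # too large to re-align; keep as is
        else:
            new_cols.extend(_expand(_affine_path(qseq[q0:q1], rseq[r0:r1])))
        prev = e
    new_cols.extend(cols[prev:])
    out: list[tuple[str, int]] = []
    for op in new_cols:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out




def _gap_path(qgap: str, rgap: str) -> list[tuple[str, int]]:
    """Edit path across one inter-anchor gap.

    Strongly one-sided gaps are treated as an indel with the smaller side
    placed by infix alignment inside the larger side; a plain unit-cost
    global path would otherwise thread a long deletion through accidental
    single-base matches, smearing it into dozens of fragments."""
    if not qgap:
        return [("D", len(rgap))] if rgap else []
    if not rgap:
        return [("I", len(qgap))]
    lq, lr = len(qgap), len(rgap)
    if lr > 4 * lq and lr - lq > 200:
        res = edlib.align(qgap.replace("N", "n"), rgap, task="path", mode="HW")
        s, e = res["locations"][0]
        path = parse_cigar(res["cigar"])
        out = ([("D", s)] if s else []) + path
        if lr - e - 1:
            out.append(("D", lr - e - 1))
        return out
    if lq > 4 * lr and lq - lr > 200:
        res = edlib.align(rgap, qgap.replace("N", "n"), task="path", mode="HW")
        s, e = res["locations"][0]
        swapped = [("I" if op == "D" else ("D" if op == "I" else op), n)
                   for op, n in parse_cigar(res["cigar"])]
        out = ([("I", s)] if s else []) + swapped
        if lq - e - 1:
            out.append(("I", lq - e - 1))
        return out
    return _edlib_path(qgap, rgap)


def _merge_runs(cigar: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, n in cigar:
        if n <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def _build_block(
    query: SequenceRecord,
    refseqs: dict[str, str],
    ref_id: str,
    strand: str,
    anchors: list[tuple[int, int, int, int]],
    params: AlignParams,
) -> AlignmentBlock:
    """Assemble a block from a chain of exact-match anchors.

    Anchors are emitted as match runs; only the inter-anchor gaps are
    aligned, so large structural gaps stay contiguous in the edit path.
    """
    qseq = query.seq if strand == "+" else revcomp(query.seq)
    rseq = refseqs[ref_id]
    q_lo, r_lo = anchors[0][0], anchors[0][2]
    q_hi, r_hi = anchors[-1][1], anchors[-1][3]
    if params.extend_to_query_ends:
        w_lo = max(0, r_lo - q_lo - 30)
        w_hi = min(len(rseq), r_hi + (len(qseq) - q_hi) + 30)
        sub_q, sub_r = qseq, rseq[w_lo:w_hi]
        if sub_q and sub_r:
            res = edlib.align(sub_q.replace("N", "n"), sub_r, task="path", mode="HW")
            loc_s, loc_e = res["locations"][0]
            q_lo, q_hi = 0, len(qseq)
            r_lo, r_hi = w_lo + loc_s, w_lo + loc_e + 1
            cigar = parse_cigar(res["cigar"])
        else:
            cigar = []
    else:
        cigar = []
        cur_q, cur_r = q_lo, r_lo
        for qs, qe, rs, re_ in anchors:
            trim = max(cur_q - qs, cur_r - rs, 0)
            qs, rs = qs + trim, rs + trim
            if qe - qs <= 0 or re_ - rs <= 0:
                continue
            cigar.extend(_gap_path(qseq[cur_q:qs], rseq[cur_r:rs]))
            cigar.append(("=", qe - qs))
            cur_q, cur_r = qe, re_
        q_hi, r_hi = cur_q, cur_r
        cigar = _merge_runs(cigar)
    # optimal unit-cost distance over the aligned region (independent of
    # the anchor-pinned path, which may be a few edits above the optimum)
    if q_hi > q_lo and r_hi > r_lo:
        edit_distance = edlib.align(
            qseq[q_lo:q_hi].replace("N", "n"), rseq[r_lo:r_hi],
            task="distance", mode="NW",
        )["editDistance"]
    else:
        edit_distance = max(q_hi - q_lo, r_hi - r_lo)
    cols0 = sum(n for _, n in cigar)
    large_gap = sum(n for op, n in cigar if op in "ID" and n >= 100)
    small_cols = cols0 - large_gap
    if (
        params.refine_gaps
        and small_cols > 0
        and 1 - (edit_distance - large_gap) / small_cols >= 0.90
    ):
        # consolidate indel placement in near-identical neighborhoods; the
        # unit-cost path is kept for diverged (junk) joins
        cigar = refine_cigar(qseq[q_lo:q_hi], rseq[r_lo:r_hi], cigar)
    n_match = sum(n for op, n in cigar if op == "=")
    cols = sum(n for _, n in cigar)
    if strand == "+":
        qs, qe = q_lo, q_hi
    else:
        qs, qe = len(qseq) - q_hi, len(qseq) - q_lo
    return AlignmentBlock(
        query_id=query.id,
        q_start=qs,
        q_end=qe,
        ref_id=ref_id,
        r_start=r_lo,
        r_end=r_hi,
        strand=strand,
        cigar=cigar,
        identity=(n_match / cols) if cols else 0.0,
        block_id=f"blk:{query.id}:{qs}-{qe}:{ref_id}:{r_lo}{'' if strand == '+' else ':-'}",
        edit_distance=edit_distance,
    )


def _gain_pen(a, b, params):
    """(gain, penalty) for chaining anchor ``a`` after ``b``; gain <= 0 or
    None penalty means incompatible."""
    dq = a[0] - b[1]
    dr = a[2] - b[3]
    li = a[1] - a[0]
    gain = min(li, li + dq, li + dr)
    if gain <= 0:
        return 0, None
    if max(dq, dr) > params.max_join_sv or min(dq, dr) > params.max_join_gap:
        return 0, None
    indel = abs(dq - dr)
    pen = 0.0
    if indel:
        pen = params.gap_open + params.gap_ext * indel
    pen += 0.02 * max(0, min(dq, dr))
    return gain, pen


def _chain_group(anchors: list[tuple[int, int, int, int]], params: AlignParams):
    """Extract collinear chains from one (reference, strand) anchor group.

    One DP pass over anchors sorted by query start. Predecessor candidates
    are the nearest ``lookback`` anchors plus the current top-scoring
    anchors, so a primary chain can bridge clutters of repeat-induced
    anchors. Chains are then peeled off greedily by descending endpoint
    score (truncating at anchors already used), which yields the primary
    alignment plus the secondary alignments of repeated sequence.
    Yields lists of anchor indices.
    """
    n = len(anchors)
    score = [0.0] * n
    prev = [-1] * n
    tops: list[int] = []  # indices of current best-scoring anchors (capped)
    TOPK = 24
    for i in range(n):
        a = anchors[i]
        best = float(a[1] - a[0])
        bp = -1
        lo = max(0, i - params.lookback)
        cands = range(lo, i)
        extra = [t for t in tops if t < lo]
        for j in itertools.chain(cands, extra):
            gain, pen = _gain_pen(a, anchors[j], params)
            if pen is None:
                continue
            cand = score[j] + gain - pen
            if cand > best:
                best, bp = cand, j
        score[i] = best
        prev[i] = bp
        if len(tops) < TOPK:
            tops.append(i)
            tops.sort(key=lambda t: -score[t])
        elif best > score[tops[-1]]:
            tops[-1] = i
            tops.sort(key=lambda t: -score[t])
    used = [False] * n
    order = sorted(range(n), key=lambda i: -score[i])
    emitted = 0
    for end in order:
        if used[end] or score[end] < params.min_chain_score:
            continue
        chain = []
        i = end
        walked_gain = 0.0
        while i >= 0 and not used[i]:
            chain.append(i)
            used[i] = True
            j = prev[i]
            if j >= 0 and not used[j]:
                gain, pen = _gain_pen(anchors[i], anchors[j], params)
                walked_gain += gain
            else:
                walked_gain += anchors[i][1] - anchors[i][0]
            i = j
        chain.reverse()
        if walked_gain < params.min_chain_score:
            continue
        yield chain
        emitted += 1
        if emitted >= params.max_chains:
            return


def chain_and_extend(
    matches: list[ExactMatch],
    query: SequenceRecord,
    reference,
    params: AlignParams | None = None,
) -> list[AlignmentBlock]:
    """Chain collinear same-strand MEMs and produce polished alignment blocks.

    ``reference`` may be a single SequenceRecord or a list of them.
    """
    params = params or AlignParams()
    refs = reference if isinstance(reference, list) else [reference]
    refseqs = {r.id: r.seq for r in refs}
    qlen = len(query.seq)
    blocks: list[AlignmentBlock] = []
    keyf = lambda m: (m.ref_id, m.strand)
    for (ref_id, strand), group in itertools.groupby(
        sorted(matches, key=keyf), key=keyf
    ):
        anchors = []
        for m in group:
            if strand == "+":
                anchors.append((m.q_start, m.q_end, m.r_start, m.r_end))
            else:
                # chain in reverse-complement query coordinates
                anchors.append((qlen - m.q_end, qlen - m.q_start, m.r_start, m.r_end))
        anchors.sort()
        for chain in _chain_group(anchors, params):
            blocks.append(
                _build_block(
                    query, refseqs, ref_id, strand,
                    [anchors[i] for i in chain], params,
                )
            )
    blocks.sort(key=lambda b: (b.ref_id, b.r_start, b.query_id, b.q_start))
    return blocks


def align_to_reference(
    queries: list[SequenceRecord],
    references: list[SequenceRecord],
    params: AlignParams | None = None,
    index: KmerIndex | None = None,
) -> list[AlignmentBlock]:
    """Seed-chain-extend every query against a shared reference index and
    flag ambiguous blocks."""
    params = params or AlignParams()
    if index is None:
        index = KmerIndex(references, params.min_mem)
    blocks: list[AlignmentBlock] = []
    for q in queries:
        mems = scan_mems(q.seq, q.id, index, params.min_mem, "+")
        if params.both_strands:
            mems += scan_mems(revcomp(q.seq), q.id, index, params.min_mem, "-")
        blocks.extend(chain_and_extend(mems, q, index.refs, params))
    return flag_ambiguity(blocks)


def split_blocks_at_large_gaps(
    blocks: list[AlignmentBlock], min_gap: int = 100
) -> list[AlignmentBlock]:
    """Split blocks at insertion/deletion runs >= min_gap into gap-free
    sub-blocks with per-segment identities (local-alignment semantics).

    Chained blocks deliberately span structural gaps; presence/absence and
    unique-region logic instead needs contiguous aligned segments whose
    identity is not diluted by a single large indel."""
    out: list[AlignmentBlock] = []
    for b in blocks:
        cuts = [g for g in b.gaps(min_len=min_gap)]
        if not cuts:
            out.append(b)
            continue
        oq = orr = 0
        bounds = []  # (oq_a, oq_b, or_a, or_b, cigar)
        cur_q, cur_r = 0, 0
        cur_cig: list[tuple[str, int]] = []
        for op, n in b.cigar:
            if op in "ID" and n >= min_gap:
                if cur_cig:
                    bounds.append((cur_q, oq, cur_r, orr, cur_cig))
                if op == "I":
                    oq += n
                else:
                    orr += n
                cur_q, cur_r, cur_cig = oq, orr, []
            else:
                cur_cig.append((op, n))
                if op in "=XI":
                    oq += n
                if op in "=XD":
                    orr += n
        if cur_cig:
            bounds.append((cur_q, oq, cur_r, orr, cur_cig))
        for si, (qa, qb, ra, rb, cig) in enumerate(bounds):
            if b.strand == "+":
                qs, qe = b.q_start + qa, b.q_start + qb
            else:
                qs, qe = b.q_end - qb, b.q_end - qa
            nm = sum(n for op, n in cig if op == "=")
            cols = sum(n for _, n in cig)
            out.append(
                AlignmentBlock(
                    query_id=b.query_id, q_start=qs, q_end=qe,
                    ref_id=b.ref_id, r_start=b.r_start + ra, r_end=b.r_start + rb,
                    strand=b.strand, cigar=cig,
                    identity=(nm / cols) if cols else 0.0,
                    ambiguous=b.ambiguous,
                    block_id=f"{b.block_id}.{si}",
                    edit_distance=sum(n for op, n in cig if op != "="),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Ambiguity


def _union_cover(intervals: list[tuple[int, int]], lo: int, hi: int) -> int:
    """Total length of [lo,hi) covered by the union of intervals."""
    cov = 0
    last = lo
    for s, e in sorted(intervals):
        s, e = max(s, lo, last), min(e, hi)
        if e > s:
            cov += e - s
            last = e
    return cov


def flag_ambiguity(
    blocks: list[AlignmentBlock], min_identity: float = 0.95
) -> list[AlignmentBlock]:
    """Mark a block ambiguous iff >50% of its query interval is covered by
    other blocks of identity >= min_identity. Nothing is removed."""
    by_query: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_query.setdefault(b.query_id, []).append(b)
    for qid, group in by_query.items():
        for b in group:
            others = [
                (o.q_start, o.q_end)
                for o in group
                if o is not b and o.identity >= min_identity
            ]
            cov = _union_cover(others, b.q_start, b.q_end)
            b.ambiguous = cov > 0.5 * b.aligned_length
    return blocks


# ---------------------------------------------------------------------------
# Self-alignment repeats


def self_repeats(
    records: list[SequenceRecord],
    min_identity: float = 0.95,
    min_length: int = 500,
    params: AlignParams | None = None,
) -> list[RepeatRegion]:
    """Regions with >min_identity similarity to sequence elsewhere in the
    genome (trivial self-match excluded; output symmetric)."""
    params = params or AlignParams(min_chain_score=min_length * 0.8)
    index = KmerIndex(records, params.min_mem)
    regions: set[tuple] = set()
    out: list[RepeatRegion] = []
    for rec in records:
        mems = scan_mems(
            rec.seq, rec.id, index, params.min_mem, "+", skip_trivial_diag=rec.id
        )
        if params.both_strands:
            mems += scan_mems(revcomp(rec.seq), rec.id, index, params.min_mem, "-")
        for b in chain_and_extend(mems, rec, records, params):
            if b.identity <= min_identity:
                continue
            if max(b.aligned_length, b.r_end - b.r_start) < min_length:
                continue
            a = (rec.id, b.q_start, b.q_end)
            p = (b.ref_id, b.r_start, b.r_end)
            if a == p:
                continue
            for x, y in ((a, p), (p, a)):
                if (x, y) not in regions:
                    regions.add((x, y))
                    out.append(
                        RepeatRegion(
                            interval=GenomicInterval(x[0], x[1], x[2]),
                            partner=GenomicInterval(y[0], y[1], y[2]),
                            identity=b.identity,
                        )
                    )
    out.sort(key=lambda r: (r.interval.seq_id, r.interval.start, r.partner.start))
    return out


# ---------------------------------------------------------------------------
# Coords table I/O (whole-genome-aligner TSV dialect; external coordinate
# tables in the same columns can be adapted in)


def write_coords(blocks: list[AlignmentBlock], path) -> None:
    import pandas as pd

    rows = [
        {
            "query_id": b.query_id,
            "q_start": b.q_start,
            "q_end": b.q_end,
            "ref_id": b.ref_id,
            "r_start": b.r_start,
            "r_end": b.r_end,
            "strand": b.strand,
            "identity": f"{b.identity:.6f}",
            "ambiguous": int(b.ambiguous),
            "cigar": "".join(f"{n}{op}" for op, n in b.cigar),
        }
        for b in blocks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_coords(path) -> list[AlignmentBlock]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    blocks = []
    for i, row in df.iterrows():
        cig = [(op, int(n)) for n, op in _CIG_RE.findall(row["cigar"])]
        blocks.append(
            AlignmentBlock(
                query_id=str(row["query_id"]),
                q_start=int(row["q_start"]),
                q_end=int(row["q_end"]),
                ref_id=str(row["ref_id"]),
                r_start=int(row["r_start"]),
                r_end=int(row["r_end"]),
                strand=str(row["strand"]),
                cigar=cig,
                identity=float(row["identity"]),
                ambiguous=bool(row.get("ambiguous", 0)),
                block_id=f"blk_file{i}",
            )
        )
    return blocks
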