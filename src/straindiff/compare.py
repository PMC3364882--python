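"""Mosaic genome painting and whole-genome coverage-distance phylogeny.

*Painting*: the query genome is cut into non-overlapping 1000 bp
fragments; for each fragment and each strain group (lab / industrial /
other) the identity of the best local alignment against any genome in the
group becomes a color channel, scaled linearly so that identity <= 97%
maps to 0 and identity 100% maps to 1.

*Phylogeny*: pairwise genome dissimilarity is a coverage distance
d(A,B) = 1 - 2*C_AB / (|A| + |B|), where C_AB counts the matching columns
of reciprocally best-aligned segments at >= 90% identity (an
identity-weighted alignable fraction; the literature definition is not
unique, so the formula is isolated here and parameterizable). Trees are
built by UPGMA with size-weighted averaging, producing rooted ultrametric
trees with equal leaf depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AlignParams, KmerIndex, chain_and_extend, scan_mems
from .io import GenomicInterval, SequenceRecord

DEFAULT_GROUPS = ("lab", "industrial", "other")


@dataclass
class MosaicFragment:
    interval: GenomicInterval
    channels: dict  # group -> value in [0, 1]
    identities: dict  # group -> best identity or None


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.matrix = m

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


@dataclass
class Tree:
    """Rooted ultrametric tree from UPGMA."""

    newick: str
    heights: dict = field(default_factory=dict)  # cluster label -> merge height

    def to_dendropy(self):
        import dendropy

        return dendropy.Tree.get(data=self.newick, schema="newick")

    def leaf_depths(self) -> dict[str, float]:
        t = self.to_dendropy()
        out = {}
        for leaf in t.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out


# ---------------------------------------------------------------------------
# Mosaic painting


def channel_value(identity: float | None, lo: float = 0.97, hi: float = 1.00) -> float:
    """Linear scaling of a best-alignment identity to a color channel."""
    if identity is None:
        return 0.0
    return float(np.clip((identity - lo) / (hi - lo), 0.0, 1.0))


def paint_mosaic(
    query_records: list[SequenceRecord],
    panel: dict[str, list[tuple[str, list[SequenceRecord]]]],
    fragment: int = 1000,
    lo: float = 0.97,
    hi: float = 1.00,
    params: AlignParams | None = None,
) -> list[MosaicFragment]:
    """Per-fragment best group identities and color channels.

    ``panel`` maps a group label to (strain_id, genome records) pairs. The
    channel is order-free within a group (a maximum over strains)."""
    if fragment < 100:
        raise ValueError("fragment size must be >= 100")
    if not panel or not any(panel.values()):
        raise ValueError("painting requires at least one group with one genome")
    params = params or AlignParams(min_mem=15, min_chain_score=50, extend_to_query_ends=True)
    indexes = {
        group: [(sid, KmerIndex(recs, params.min_mem)) for sid, recs in strains]
        for group, strains in panel.items()
    }
    out: list[MosaicFragment] = []
    for rec in query_records:
        for s in range(0, len(rec.seq), fragment):
            e = min(s + fragment, len(rec.seq))
            frag = SequenceRecord(f"{rec.id}:{s}", rec.seq[s:e])
            identities: dict[str, float | None] = {}
            for group, idxs in indexes.items():
                best = None
                for _sid, idx in idxs:
                    mems = scan_mems(frag.seq, frag.id, idx, params.min_mem, "+")
                    bls = chain_and_extend(mems, frag, idx.refs, params)
                    if bls:
                        top = max(bls, key=lambda b: b.score)
                        best = top.identity if best is None else max(best, top.identity)
                identities[group] = best
            out.append(
                MosaicFragment(
                    GenomicInterval(rec.id, s, e),
                    {g: channel_value(identities[g], lo, hi) for g in identities},
                    identities,
                )
            )
    return out


def mosaic_to_frame(fragments: list[MosaicFragment]):
    import pandas as pd

    groups = sorted(fragments[0].channels) if fragments else []
    rows = []
    for f in fragments:
        row = {"chr": f.interval.seq_id, "start": f.interval.start, "end": f.interval.end}
        for g in groups:
            row[f"channel_{g}"] = f.channels[g]
            row[f"identity_{g}"] = f.identities[g] if f.identities[g] is not None else ""
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Coverage distance


def _directional_match_mass(
    a_records: list[SequenceRecord],
    b_index: KmerIndex,
    params: AlignParams,
    min_identity: float,
) -> float:
    """Matching columns of best-per-position alignments of A against B."""
    b_free = {r.id: np.ones(len(r.seq), dtype=bool) for r in b_index.refs}
    a_free = {r.id: np.ones(len(r.seq), dtype=bool) for r in a_records}
    blocks = []
    for rec in a_records:
        mems = scan_mems(rec.seq, rec.id, b_index, params.min_mem, "+")
        blocks.extend(chain_and_extend(mems, rec, b_index.refs, params))
    blocks.sort(key=lambda b: (-b.identity, -b.aligned_length, b.query_id, b.q_start))
    mass = 0.0
    for b in blocks:
        if b.identity < min_identity:
            continue
        fa = a_free[b.query_id][b.q_start : b.q_end]
        fb = b_free[b.ref_id][b.r_start : b.r_end]
        frac = min(fa.mean() if fa.size else 0.0, fb.mean() if fb.size else 0.0)
        if frac <= 0:
            continue
        mass += b.n_match * frac
        fa[:] = False
        fb[:] = False
    return mass


def coverage_distance(
    genome_a: list[SequenceRecord],
    genome_b: list[SequenceRecord],
    min_identity: float = 0.90,
    params: AlignParams | None = None,
) -> float:
    """Whole-genome coverage distance in [0, 1] (0 on self; symmetric)."""
    if not genome_a or not genome_b:
        raise ValueError("both genomes must be non-empty")
    params = params or AlignParams(min_chain_score=100)
    la = sum(len(r.seq) for r in genome_a)
    lb = sum(len(r.seq) for r in genome_b)
    c_ab = _directional_match_mass(genome_a, KmerIndex(genome_b, params.min_mem), params, min_identity)
    c_ba = _directional_match_mass(genome_b, KmerIndex(genome_a, params.min_mem), params, min_identity)
    c = 0.5 * (c_ab + c_ba)
    return float(np.clip(1.0 - 2.0 * c / (la + lb), 0.0, 1.0))


def distance_matrix(
    genomes: list[tuple[str, list[SequenceRecord]]],
    min_identity: float = 0.90,
    params: AlignParams | None = None,
) -> DistanceMatrix:
    n = len(genomes)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = coverage_distance(genomes[i][1], genomes[j][1], min_identity, params)
            m[i, j] = m[j, i] = d
    return DistanceMatrix([g[0] for g in genomes], m)


# ---------------------------------------------------------------------------
# UPGMA


def upgma(dm: DistanceMatrix) -> Tree:
    """UPGMA with size-weighted (proportional) averaging.

    Merge ties are broken by the lexicographically smallest pair of cluster
    labels; leaf heights are half the merge distance, so leaf depths are
    equal (ultrametric)."""
    if len(dm.ids) < 2:
        raise ValueError("UPGMA needs at least two taxa")
    # cluster state: label -> (size, height, newick)
    clusters: dict[str, tuple[int, float, str]] = {
        name: (1, 0.0, name) for name in dm.ids
    }
    dist: dict[frozenset, float] = {}
    for i, a in enumerate(dm.ids):
        for j in range(i + 1, len(dm.ids)):
            dist[frozenset((a, dm.ids[j]))] = float(dm.matrix[i, j])
    heights: dict[str, float] = {}
    while len(clusters) > 1:
        best = min(
            dist.items(), key=lambda kv: (kv[1], tuple(sorted(kv[0])))
        )
        pair, d = best
        a, b = sorted(pair)
        sa, ha, na = clusters.pop(a)
        sb, hb, nb = clusters.pop(b)
        h = d / 2.0
        label = a  # keep the smaller label for deterministic tie-breaks
        newick = f"({na}:{h - ha:.10g},{nb}:{h - hb:.10g})"
        heights[f"{a}+{b}"] = h
        for other in list(clusters):
            key_a, key_b = frozenset((a, other)), frozenset((b, other))
            da, db = dist.pop(key_a), dist.pop(key_b)
            dist[frozenset((label, other))] = (sa * da + sb * db) / (sa + sb)
        del dist[pair]
        clusters[label] = (sa + sb, h, newick)
    (_size, _h, newick) = next(iter(clusters.values()))
    return Tree(newick=newick + ";", heights=heights)
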