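"""Aligner correctness: MEM enumeration vs a brute-force oracle, polished
edit paths vs an independent dynamic-programming oracle, ambiguity and
self-repeat semantics."""

from __future__ import annotations

import random

import numpy as np
import pytest

from straindiff.align import (
    AlignParams,
    chain_and_extend,
    find_mems,
    flag_ambiguity,
    self_repeats,
    split_blocks_at_large_gaps,
)
from straindiff.io import SequenceRecord, revcomp

from conftest import mutate_seq, random_dna


# ---------------------------------------------------------------------------
# independent oracles (kept free of straindiff internals)


def brute_force_mems(q: str, r: str, min_len: int) -> set[tuple[int, int, int]]:
    """All maximal exact matches >= min_len by explicit diagonal scanning."""
    out = set()
    for d in range(-len(q) + 1, len(r)):
        i, j = (max(0, -d), max(0, d))
        run = 0
        while i <= len(q) and j <= len(r):
            match = i < len(q) and j < len(r) and q[i] == r[j] and q[i] != "N"
            if match:
                run += 1
            else:
                if run >= min_len:
                    out.add((i - run, j - run, run))
                run = 0
            i += 1
            j += 1
    return out


def edit_distance_dp(a: str, b: str) -> int:
    """Full quadratic Levenshtein distance (numpy rows)."""
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, start=1):
        cur = np.empty(len(b) + 1, dtype=np.int64)
        cur[0] = i
        sub = prev[:-1] + (np.frombuffer(b.encode(), dtype=np.uint8) != ord(ca))
        for j in range(1, len(b) + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, sub[j - 1])
        prev = cur
    return int(prev[-1])


def mutated_pair(seed: int, n: int = 250):
    """A high-identity random pair: SNVs plus a couple of small indels."""
    rng = random.Random(seed)
    ref = random_dna(n, seed)
    q = list(ref)
    for _ in range(rng.randint(1, 5)):
        p = rng.randrange(10, n - 10)
        q[p] = rng.choice([b for b in "ACGT" if b != q[p]])
    for _ in range(rng.randint(0, 2)):
        p = rng.randrange(20, n - 30)
        if rng.random() < 0.5:
            del q[p : p + rng.randint(1, 6)]
        else:
            q[p:p] = random_dna(rng.randint(1, 6), seed + 99)
    return "".join(q), ref


# ---------------------------------------------------------------------------


class TestFindMems:
    def test_identical_sequences_single_full_match(self):
        s = random_dna(500, 1)
        mems = find_mems(SequenceRecord("q", s), SequenceRecord("r", s), 20)
        assert [(m.q_start, m.q_end, m.r_start, m.r_end) for m in mems] == [
            (0, 500, 0, 500)
        ]

    def test_disjoint_sequences_empty(self):
        q = SequenceRecord("q", random_dna(300, 2))
        r = SequenceRecord("r", random_dna(300, 3))
        # random 300-mers share no 20-mer with overwhelming probability
        assert find_mems(q, r, 20) == []

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        # embed shared segments so matches exist
        core = random_dna(60, seed + 500)
        q = random_dna(70, seed) + core + random_dna(70, seed + 1)
        r = random_dna(50, seed + 2) + core + random_dna(90, seed + 3)
        got = {
            (m.q_start, m.r_start, m.length)
            for m in find_mems(SequenceRecord("q", q), SequenceRecord("r", r), 15)
        }
        assert got == brute_force_mems(q, r, 15)

    def test_reverse_strand_matches(self):
        core = random_dna(80, 7)
        q = random_dna(40, 8) + revcomp(core) + random_dna(40, 9)
        r = random_dna(30, 10) + core + random_dna(30, 11)
        mems = find_mems(SequenceRecord("q", q), SequenceRecord("r", r), 20,
                         both_strands=True)
        minus = [m for m in mems if m.strand == "-"]
        assert minus, "reverse-complement match must be found"
        m = minus[0]
        assert revcomp(q[m.q_start : m.q_end]) == r[m.r_start : m.r_end]

    def test_n_never_matches(self):
        s = random_dna(100, 12)
        q = s[:50] + "N" * 10 + s[60:]
        mems = find_mems(SequenceRecord("q", q), SequenceRecord("r", q), 20)
        assert all("N" not in q[m.q_start : m.q_end] for m in mems)

    def test_min_length_precondition(self):
        with pytest.raises(ValueError):
            find_mems(SequenceRecord("q", "ACGT"), SequenceRecord("r", "ACGT"), 5)


class TestChainAndExtend:
    def test_single_anchor_identity_one(self):
        s = random_dna(400, 20)
        q, r = SequenceRecord("q", s), SequenceRecord("r", s)
        blocks = chain_and_extend(find_mems(q, r, 20), q, r)
        assert len(blocks) == 1
        assert blocks[0].identity == 1.0
        assert blocks[0].cigar == [("=", 400)]
        assert blocks[0].edit_distance == 0

    def test_two_substitutions_identity(self):
        r = random_dna(204, 21)
        q = list(r)
        q[100] = "A" if r[100] != "A" else "C"
        q[102] = "A" if r[102] != "A" else "C"
        q = "".join(q)
        qr, rr = SequenceRecord("q", q), SequenceRecord("r", r)
        blocks = chain_and_extend(find_mems(qr, rr, 20), qr, rr)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.edit_distance == 2 == edit_distance_dp(q, r)
        assert b.identity == pytest.approx(202 / 204)

    @pytest.mark.parametrize("seed", range(15))
    def test_edit_distance_equals_dp_oracle(self, seed):
        q, r = mutated_pair(seed)
        qr, rr = SequenceRecord("q", q), SequenceRecord("r", r)
        blocks = chain_and_extend(find_mems(qr, rr, 15), qr, rr)
        assert blocks
        b = max(blocks, key=lambda b: b.aligned_length)
        sub_q = q[b.q_start : b.q_end]
        sub_r = r[b.r_start : b.r_end]
        assert b.edit_distance == edit_distance_dp(sub_q, sub_r)

    def test_identity_recomputable_from_edit_path(self, small_blocks):
        for b in small_blocks:
            assert b.identity == pytest.approx(b.recompute_identity())

    def test_opposite_strand_anchors_make_separate_blocks(self):
        a, bseg = random_dna(150, 30), random_dna(150, 31)
        r = a + random_dna(50, 32) + bseg
        q = a + random_dna(50, 33) + revcomp(bseg)
        qr, rr = SequenceRecord("q", q), SequenceRecord("r", r)
        blocks = chain_and_extend(
            find_mems(qr, rr, 20, both_strands=True), qr, rr,
            AlignParams(min_chain_score=50),
        )
        strands = {b.strand for b in blocks}
        assert strands == {"+", "-"}

    def test_large_deletion_stays_contiguous(self):
        # a 2 kb deletion must appear as one D run, not a smear of pieces
        r = random_dna(12_000, 34)
        q = r[:5000] + r[7000:]
        qr, rr = SequenceRecord("q", q), SequenceRecord("r", r)
        blocks = chain_and_extend(find_mems(qr, rr, 20), qr, rr)
        b = max(blocks, key=lambda b: b.aligned_length)
        dels = [g for g in b.gaps(min_len=100) if g[0] == "D"]
        assert len(dels) == 1
        assert dels[0][3] == 2000
        assert dels[0][1] == 5000


class TestAmbiguity:
    def test_single_block_not_ambiguous(self):
        s = random_dna(300, 40)
        q, r = SequenceRecord("q", s), SequenceRecord("r", s)
        blocks = flag_ambiguity(chain_and_extend(find_mems(q, r, 20), q, r))
        assert [b.ambiguous for b in blocks] == [False]

    def test_reference_duplication_flags_query_interval(self):
        # two reference copies of one query segment -> both blocks cover the
        # same query interval -> ambiguous
        seg = random_dna(800, 41)
        r = seg + random_dna(300, 42) + seg
        q = seg
        qr, rr = SequenceRecord("q", q), SequenceRecord("r", r)
        blocks = flag_ambiguity(
            chain_and_extend(find_mems(qr, rr, 20), qr, rr,
                             AlignParams(min_chain_score=100))
        )
        full = [b for b in blocks if b.aligned_length >= 700]
        assert len(full) == 2
        assert all(b.ambiguous for b in full)

    def test_reference_side_overlap_is_not_ambiguity(self):
        # two query segments aligning to one reference locus overlap on the
        # reference, not on the query -> not ambiguous
        seg = random_dna(800, 43)
        q = seg + random_dna(300, 44) + seg
        r = seg
        qr, rr = SequenceRecord("q", q), SequenceRecord("r", r)
        blocks = flag_ambiguity(
            chain_and_extend(find_mems(qr, rr, 20), qr, rr,
                             AlignParams(min_chain_score=100))
        )
        full = [b for b in blocks if b.aligned_length >= 700]
        assert len(full) == 2
        assert not any(b.ambiguous for b in full)


class TestSelfRepeats:
    def test_exact_duplication_reported_symmetrically(self):
        g = random_dna(4000, 50)
        genome = g + g[500:1500] + random_dna(500, 51)
        reps = self_repeats([SequenceRecord("chr1", genome)], min_length=500)
        pairs = {(r.interval.start, r.interval.end, r.partner.start, r.partner.end)
                 for r in reps}
        assert (500, 1500, 4000, 5000) in pairs
        assert (4000, 5000, 500, 1500) in pairs

    def test_repeat_free_genome_empty(self):
        reps = self_repeats([SequenceRecord("chr1", random_dna(5000, 52))],
                            min_length=500)
        assert reps == []

    def test_identity_threshold_bracketing(self):
        g = random_dna(4000, 53)
        copy = g[500:1500]
        lo = mutate_seq(copy, 0.07, 1)  # ~93% identity -> below cut
        hi = mutate_seq(copy, 0.04, 2)  # ~96% identity -> above cut
        genome_lo = g + lo + random_dna(400, 54)
        genome_hi = g + hi + random_dna(400, 54)
        reps_lo = self_repeats([SequenceRecord("chr1", genome_lo)], min_length=500)
        reps_hi = self_repeats([SequenceRecord("chr1", genome_hi)], min_length=500)
        assert reps_lo == []
        assert any(
            r.interval.start >= 3900 or r.partner.start >= 3900 for r in reps_hi
        )
        assert all(r.identity > 0.95 for r in reps_hi)


class TestSplitBlocks:
    def test_segments_partition_and_identity(self):
        r = random_dna(3000, 60)
        q = r[:1000] + r[1500:]
        qr, rr = SequenceRecord("q", q), SequenceRecord("r", r)
        blocks = chain_and_extend(find_mems(qr, rr, 20), qr, rr)
        segs = split_blocks_at_large_gaps(blocks, min_gap=100)
        assert len(segs) == 2
        assert all(s.identity == 1.0 for s in segs)
        assert sum(s.aligned_length for s in segs) == len(q)
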