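"""Variant calling and annotation: filter thresholds, tandem-repeat
detection vs an exhaustive oracle, gene effects vs a full-translation
oracle, and the edit-consistency property."""

from __future__ import annotations

import random

import numpy as np
import pytest
from Bio.Seq import Seq

from straindiff.align import AlignmentBlock, chain_and_extend, find_mems
from straindiff.io import GeneModel, GenomicInterval, SequenceRecord, revcomp
from straindiff.variants import (
    TandemRepeatLocus,
    VariantCall,
    annotate_variants,
    call_variants,
    detect_tandem_repeats,
)

from conftest import random_dna


def _block(qseq, rseq, cigar, identity=None, **kw):
    nm = sum(n for op, n in cigar if op == "=")
    cols = sum(n for _, n in cigar)
    return AlignmentBlock(
        query_id=kw.get("query_id", "q"),
        q_start=0,
        q_end=sum(n for op, n in cigar if op in "=XI"),
        ref_id=kw.get("ref_id", "chr1"),
        r_start=kw.get("r_start", 0),
        r_end=kw.get("r_start", 0) + sum(n for op, n in cigar if op in "=XD"),
        strand="+",
        cigar=cigar,
        identity=identity if identity is not None else nm / cols,
        block_id=kw.get("block_id", "b1"),
        ambiguous=kw.get("ambiguous", False),
    )


class TestCallVariants:
    def test_low_identity_block_contributes_nothing(self):
        # identity below the 97% alignment threshold: no calls at all
        r = random_dna(100, 1)
        q = list(r)
        for p in (10, 30, 50, 70, 90):
            q[p] = "A" if r[p] != "A" else "C"
        q = "".join(q)
        cigar = []
        for i, (a, b) in enumerate(zip(q, r)):
            cigar.append(("=" if a == b else "X", 1))
        blk = _block(q, r, cigar, identity=0.96)
        calls = call_variants([blk], {"q": q}, {"chr1": r})
        assert calls == []

    def test_three_bp_gap_one_deletion(self):
        r = random_dna(103, 2)
        q = r[:50] + r[53:]
        cigar = [("=", 50), ("D", 3), ("=", 50)]
        calls = call_variants([_block(q, r, cigar)], {"q": q}, {"chr1": r})
        dels = [c for c in calls if c.kind == "deletion"]
        assert len(dels) == 1
        assert dels[0].length == 3

    def test_ambiguous_blocks_dropped(self):
        r = random_dna(100, 3)
        q = r[:50] + ("A" if r[50] != "A" else "C") + r[51:]
        cigar = [("=", 50), ("X", 1), ("=", 49)]
        blk = _block(q, r, cigar, ambiguous=True)
        assert call_variants([blk], {"q": q}, {"chr1": r}) == []

    def test_gap_run_over_90_is_structural_not_indel(self):
        r = random_dna(1200, 4)
        q = r[:500] + r[620:]
        cigar = [("=", 500), ("D", 120), ("=", 580)]
        structural = []
        calls = call_variants([_block(q, r, cigar)], {"q": q}, {"chr1": r},
                              structural_out=structural)
        assert all(c.kind == "snv" or c.length <= 90 for c in calls)
        assert not any(c.kind != "snv" for c in calls)
        assert [(s.kind, s.length, s.ref_start) for s in structural] == [
            ("deletion", 120, 500)
        ]

    def test_left_normalization_vcf_style(self):
        # deleting one unit of 'CAG' anywhere in the run reports the
        # leftmost representation
        pad = random_dna(100, 5)
        r = pad + "CAG" * 5 + "TT" + pad
        q = pad + "CAG" * 4 + "TT" + pad
        cigar = [("=", 106), ("D", 3), ("=", len(q) - 106)]
        calls = call_variants([_block(q, r, cigar)], {"q": q}, {"chr1": r})
        d = [c for c in calls if c.kind == "deletion"][0]
        assert d.pos == 100  # shifted to the start of the CAG array
        assert d.ref == "CAG"

    def test_unknown_reference_errors(self):
        blk = _block("ACGT", "ACGT", [("=", 4)], ref_id="nope")
        with pytest.raises(KeyError):
            call_variants([blk], {"q": "ACGT"}, {"chr1": "ACGT"})

    def test_edit_consistency_applying_calls_reconstructs_query(self, small_pair,
                                                                 small_contigs,
                                                                 small_blocks):
        bundle, _query, _truth = small_pair
        contigs, _ = small_contigs
        qseqs = {c.id: c.seq for c in contigs}
        calls = call_variants(small_blocks, qseqs, bundle.seqs)
        by_block = {}
        for c in calls:
            by_block.setdefault(c.block_id, []).append(c)
        checked = 0
        for b in small_blocks:
            if b.ambiguous or b.identity < 0.97 or b.block_id not in by_block:
                continue
            # rebuild the query interval from the reference plus this
            # block's calls (block-local, no large gaps in these contigs)
            if any(n > 90 for op, n in b.cigar if op in "ID"):
                continue
            ref = bundle.seqs[b.ref_id]
            edits = sorted(by_block[b.block_id], key=lambda c: c.pos, reverse=True)
            s = list(ref[b.r_start : b.r_end])
            for c in edits:
                off = c.pos - b.r_start
                if c.kind == "snv":
                    s[off] = c.alt
                elif c.kind == "deletion":
                    del s[off : off + len(c.ref)]
                else:
                    s[off:off] = list(c.alt)
            rebuilt = "".join(s)
            expected = qseqs[b.query_id][b.q_start : b.q_end]
            if b.strand == "-":
                expected = revcomp(expected)
            assert rebuilt == expected
            checked += 1
        assert checked >= 3

    def test_no_indel_exceeds_90(self, small_pair, small_contigs, small_blocks):
        bundle, _, _ = small_pair
        contigs, _ = small_contigs
        calls = call_variants(small_blocks, {c.id: c.seq for c in contigs}, bundle.seqs)
        assert all(c.length <= 90 for c in calls)

    def test_call_invariants_enforced(self):
        with pytest.raises(ValueError):
            VariantCall("snv", "c", 0, "A", "A")
        with pytest.raises(ValueError):
            VariantCall("deletion", "c", 0, "A" * 91, "")
        with pytest.raises(ValueError):
            VariantCall("insertion", "c", 0, "", "")


class TestTandemRepeats:
    def brute_force(self, seq, max_unit, min_span_units=2):
        """Exhaustive (unit, start) scan for maximal perfect arrays."""
        found = set()
        n = len(seq)
        for u in range(1, max_unit + 1):
            for s in range(n - u):
                if s > 0 and s - 1 + u < n and seq[s - 1] == seq[s - 1 + u]:
                    continue  # not left-maximal
                e = s + u
                while e < n and seq[e] == seq[e - u]:
                    e += 1
                if e - s >= u * min_span_units:
                    found.add((s, e, u))
        return found

    def test_embedded_trinucleotide_array(self):
        seq = "GATTTCCA" + "ACG" * 3 + "TTGAC"
        loci = detect_tandem_repeats(SequenceRecord("s", seq), max_unit=10,
                                     min_span_bp=8)
        hit = [t for t in loci if t.unit == 3]
        assert len(hit) == 1
        t = hit[0]
        assert (t.interval.start, t.interval.end) == (8, 17)
        assert t.copies == 3

    def test_homopolymer_run(self):
        seq = "GCTGC" + "A" * 12 + "GCTTG"
        loci = detect_tandem_repeats(SequenceRecord("s", seq), max_unit=6,
                                     min_span_bp=8)
        assert any(t.unit == 1 and t.copies == 12 for t in loci)

    def test_recovers_planted_simulation_loci(self, small_bundle):
        loci = detect_tandem_repeats(small_bundle.records, max_unit=60, min_span_bp=10)
        spans = {(t.interval.seq_id, t.interval.start, t.interval.end) for t in loci}
        for t in small_bundle.tandems:
            iv = t.interval
            # allow boundary extension when flanking bases extend the array
            assert any(c == iv.seq_id and s <= iv.start and e >= iv.end
                       for c, s, e in spans), iv

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = random.Random(seed)
        seq = random_dna(80, seed) + rng.choice(["ACT", "GA", "TTAC"]) * rng.randint(3, 6) + random_dna(80, seed + 1)
        loci = detect_tandem_repeats(SequenceRecord("s", seq), max_unit=8,
                                     min_span_bp=6)
        oracle = self.brute_force(seq, max_unit=8)
        # every reported locus is a genuine maximal array per the oracle,
        # with the smallest unit for its span
        for t in loci:
            s, e, u = t.interval.start, t.interval.end, t.unit
            matching = {(os, oe) for os, oe, ou in oracle if ou == u}
            assert (s, e) in matching
        # the planted array around position 80 is reported
        assert any(t.interval.start <= 80 < t.interval.end for t in loci)


class TestAnnotation:
    def _gene(self, chrom="chr1", start=100, n_codons=50, strand="+"):
        rng = random.Random(7)
        codons = ["ATG"]
        aas = "ACDEFGHIKLMNPQRSTVWY"
        table = {}
        while len(codons) < n_codons - 1:
            c = random_dna(3, rng.randrange(10**6))
            if c not in ("TAA", "TAG", "TGA", "ATG"):
                codons.append(c)
        codons.append("TAA")
        cds = "".join(codons)
        iv = GenomicInterval(chrom, start, start + len(cds), strand)
        gene = GeneModel("G1", iv, [iv], strand)
        genomic = cds if strand == "+" else revcomp(cds)
        ref = random_dna(start, 11) + genomic + random_dna(60, 12)
        return gene, {chrom: ref}, cds

    def test_synonymous_change_is_sense(self):
        gene, refs, cds = self._gene()
        # find a codon whose third-position change is synonymous
        for ci in range(1, 40):
            codon = cds[3 * ci : 3 * ci + 3]
            for alt in "ACGT":
                mut = codon[:2] + alt
                if mut != codon and str(Seq(mut).translate()) == str(Seq(codon).translate()):
                    pos = gene.interval.start + 3 * ci + 2
                    call = VariantCall("snv", "chr1", pos, refs["chr1"][pos], alt,
                                       variant_id="v1")
                    (ann,) = annotate_variants([call], [gene], [], refs)
                    assert ann.effect == "sense"
                    assert ann.frame_preserved
                    return
        pytest.fail("no synonymous site found")

    def test_inframe_deletion_midgene(self):
        gene, refs, cds = self._gene()
        pos = gene.interval.start + 12
        call = VariantCall("deletion", "chr1", pos, refs["chr1"][pos:pos+3], "",
                           variant_id="v1")
        (ann,) = annotate_variants([call], [gene], [], refs)
        assert ann.effect == "inframe_indel"
        assert ann.frame_preserved

    def test_frameshift_iff_length_not_multiple_of_three(self):
        gene, refs, _ = self._gene()
        for L, expect in [(1, "frameshift"), (2, "frameshift"), (3, "inframe_indel"),
                          (4, "frameshift"), (6, "inframe_indel")]:
            pos = gene.interval.start + 15
            call = VariantCall("deletion", "chr1", pos, refs["chr1"][pos:pos+L], "",
                               variant_id="v")
            (ann,) = annotate_variants([call], [gene], [], refs)
            assert ann.effect == expect, L

    def test_start_codon_hit(self):
        gene, refs, _ = self._gene()
        pos = gene.interval.start  # the A of ATG
        alt = "C" if refs["chr1"][pos] != "C" else "G"
        call = VariantCall("snv", "chr1", pos, refs["chr1"][pos], alt, variant_id="v")
        (ann,) = annotate_variants([call], [gene], [], refs)
        assert ann.effect == "start_stop_altered"
        assert not ann.frame_preserved

    def test_intergenic(self):
        gene, refs, _ = self._gene()
        call = VariantCall("snv", "chr1", 5, refs["chr1"][5],
                           "C" if refs["chr1"][5] != "C" else "G", variant_id="v")
        (ann,) = annotate_variants([call], [gene], [], refs)
        assert ann.effect == "intergenic"

    def test_tandem_repeat_flag_set(self):
        gene, refs, _ = self._gene()
        rep = TandemRepeatLocus(GenomicInterval("chr1", 3, 9), 3, 2.0)
        call = VariantCall("snv", "chr1", 5, refs["chr1"][5],
                           "C" if refs["chr1"][5] != "C" else "G", variant_id="v")
        annotate_variants([call], [gene], [rep], refs)
        assert call.in_tandem_repeat

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_snv_effects_match_full_translation_oracle(self, strand):
        gene, refs, cds = self._gene(strand=strand)
        rng = random.Random(13)
        n_codons = len(cds) // 3
        for _ in range(150):
            cds_pos = rng.randrange(len(cds))
            ref_base_cds = cds[cds_pos]
            alt_cds = rng.choice([b for b in "ACGT" if b != ref_base_cds])
            # map CDS offset to genomic position / allele
            if strand == "+":
                gpos = gene.interval.start + cds_pos
                galt = alt_cds
            else:
                gpos = gene.interval.end - 1 - cds_pos
                galt = revcomp(alt_cds)
            call = VariantCall("snv", "chr1", gpos, refs["chr1"][gpos], galt,
                               variant_id="v")
            (ann,) = annotate_variants([call], [gene], [], refs)
            # oracle: translate the full mutant CDS
            mutant = cds[:cds_pos] + alt_cds + cds[cds_pos + 1 :]
            p_ref = str(Seq(cds).translate())
            p_mut = str(Seq(mutant).translate())
            ci = cds_pos // 3
            if p_ref == p_mut:
                expect = "sense"
            elif ci == 0 and mutant[:3] != "ATG":
                expect = "start_stop_altered"
            elif ci == n_codons - 1 and not p_mut.endswith("*"):
                expect = "start_stop_altered"
            else:
                expect = "missense"
            assert ann.effect == expect, (cds_pos, strand)

    def test_incomplete_cds_skipped_with_warning(self, caplog):
        gene, refs, cds = self._gene()
        bad_iv = GenomicInterval("chr1", gene.interval.start, gene.interval.end - 1, "+")
        bad = GeneModel("G2", bad_iv, [bad_iv], "+")
        pos = bad_iv.start + 10
        call = VariantCall("snv", "chr1", pos, refs["chr1"][pos],
                           "C" if refs["chr1"][pos] != "C" else "G", variant_id="v")
        import logging

        with caplog.at_level(logging.WARNING):
            anns = annotate_variants([call], [bad], [], refs)
        assert anns == []
        assert "not divisible by 3" in caplog.text
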