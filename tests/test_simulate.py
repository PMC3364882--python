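"""Simulator contracts: determinism, exact count/length bookkeeping,
feature geometry, fragmentation conservation, and Poisson depth."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from straindiff.simulate import (
    PlacementError,
    SimulationPlan,
    fragment_assembly,
    gc_bias_profile,
    generate_reference,
    mutate_genome,
    simulate_depth,
)


class TestGenerateReference:
    def test_deterministic_given_seed(self, small_plan, small_bundle):
        again = generate_reference(small_plan)
        assert all(a.seq == b.seq for a, b in zip(small_bundle.records, again.records))
        assert [t.locus_id for t in again.transposons] == [
            t.locus_id for t in small_bundle.transposons
        ]

    def test_zero_transposons_empty_annotation(self):
        plan = SimulationPlan(seed=1, n_chromosomes=1, chromosome_length=30_000,
                              n_genes=5, transposon_counts={}, n_tandem_repeat_loci=3)
        bundle = generate_reference(plan)
        assert bundle.transposons == []

    def test_transposon_count_and_length(self):
        plan = SimulationPlan(seed=2, n_chromosomes=2, chromosome_length=100_000,
                              n_genes=5, transposon_counts={"Ty1": 6, "Ty2": 4},
                              n_tandem_repeat_loci=0)
        bundle = generate_reference(plan)
        assert len(bundle.transposons) == 10
        assert all(len(t.interval) == 6000 for t in bundle.transposons)

    def test_ltr_identical_within_family(self):
        plan = SimulationPlan(seed=3, n_chromosomes=1, chromosome_length=80_000,
                              n_genes=0, transposon_counts={"Ty1": 3},
                              n_tandem_repeat_loci=0)
        b = generate_reference(plan)
        seq = b.records[0].seq
        ltrs = set()
        for t in b.transposons:
            iv = t.interval
            ltrs.add(seq[iv.start : iv.start + t.ltr_length])
            ltrs.add(seq[iv.end - t.ltr_length : iv.end])
        assert len(ltrs) == 1

    def test_tandem_arrays_are_perfect(self, small_bundle):
        for t in small_bundle.tandems:
            iv = t.interval
            seq = {r.id: r.seq for r in small_bundle.records}[iv.seq_id]
            arr = seq[iv.start : iv.end]
            unit = arr[: t.unit]
            assert arr == unit * t.copies
            assert 3 <= t.unit <= 60
            assert 5 <= t.copies <= 40

    def test_genes_avoid_transposons(self, small_bundle):
        for g in small_bundle.genes:
            for t in small_bundle.transposons:
                assert not g.interval.overlaps(t.interval)

    def test_gene_models_translate_cleanly(self, small_bundle):
        refs = small_bundle.seqs
        for g in small_bundle.genes:
            cds = g.cds_sequence(refs)
            assert len(cds) % 3 == 0
            assert cds[:3] == "ATG"
            assert cds[-3:] in {"TAA", "TAG", "TGA"}
            assert not any(cds[i:i+3] in {"TAA", "TAG", "TGA"}
                           for i in range(3, len(cds) - 3, 3))

    def test_capacity_error(self):
        plan = SimulationPlan(seed=4, n_chromosomes=1, chromosome_length=15_000,
                              n_genes=0, transposon_counts={"Ty1": 5},
                              n_tandem_repeat_loci=0)
        with pytest.raises(PlacementError):
            generate_reference(plan)


class TestMutateGenome:
    def test_identity_when_all_zero(self):
        plan = SimulationPlan(seed=5, n_chromosomes=1, chromosome_length=40_000,
                              n_genes=10, transposon_counts={"Ty1": 1},
                              n_tandem_repeat_loci=5, snv_count=0, indel_count=0)
        bundle = generate_reference(plan)
        query, truth = mutate_genome(bundle, plan)
        assert query[0].seq == bundle.records[0].seq
        assert not truth.snvs and not truth.indels and not truth.deletions

    def test_exact_snv_count(self, small_pair, small_plan):
        _, _, truth = small_pair
        assert len(truth.snvs) == small_plan.snv_count

    def test_length_bookkeeping_reconciles(self, small_pair, small_bundle):
        _, query, truth = small_pair
        delta = sum(len(r.seq) for r in query) - sum(small_bundle.lengths.values())
        assert delta == truth.length_delta()

    def test_excision_leaves_single_terminal_repeat(self):
        plan = SimulationPlan(seed=6, n_chromosomes=1, chromosome_length=60_000,
                              n_genes=5, transposon_counts={"Ty1": 2},
                              n_tandem_repeat_loci=0, snv_count=0, indel_count=0,
                              excised_transposon_count=1)
        bundle = generate_reference(plan)
        query, truth = mutate_genome(bundle, plan)
        excised = [l for l, s in truth.transposon_states.items() if s == "excised"]
        assert len(excised) == 1
        # closed-form length bookkeeping: query lost (element - one LTR)
        lost = plan.transposon_length - plan.ltr_length
        assert sum(bundle.lengths.values()) - sum(len(r.seq) for r in query) == lost
        # remnant equals the family LTR sequence
        chrom, qs, qe = truth.transposon_query_intervals[excised[0]]
        remnant = query[0].seq[qs:qe]
        t = next(t for t in bundle.transposons if t.locus_id == excised[0])
        ref_ltr = bundle.seqs[chrom][t.interval.start : t.interval.start + t.ltr_length]
        assert remnant == ref_ltr

    def test_snv_truth_alleles_match_sequences(self, small_pair, small_bundle):
        _, query, truth = small_pair
        refs = small_bundle.seqs
        qseqs = {r.id: r.seq for r in query}
        for s in truth.snvs:
            assert refs[s.chrom][s.ref_pos] == s.ref
            assert qseqs[s.chrom][s.query_pos] == s.alt
            assert s.ref != s.alt

    def test_tandem_indel_lengths_are_unit_multiples(self):
        plan = SimulationPlan(seed=7, n_chromosomes=1, chromosome_length=80_000,
                              n_genes=5, transposon_counts={},
                              n_tandem_repeat_loci=20, snv_count=0,
                              indel_count=20, indel_tandem_fraction=1.0)
        bundle = generate_reference(plan)
        _, truth = mutate_genome(bundle, plan)
        in_tandem = [i for i in truth.indels if i.in_tandem]
        assert in_tandem
        units = {(t.interval.seq_id, t.interval.start, t.interval.end): t.unit
                 for t in bundle.tandems}
        for i in in_tandem:
            unit = next(u for (c, s, e), u in units.items()
                        if c == i.chrom and s <= i.ref_pos <= e)
            assert i.length % unit == 0

    def test_unique_insertions_share_no_20mer_with_reference(self):
        plan = SimulationPlan(seed=8, n_chromosomes=1, chromosome_length=40_000,
                              n_genes=0, transposon_counts={}, n_tandem_repeat_loci=0,
                              snv_count=0, indel_count=0,
                              unique_insertion_specs=[1500])
        bundle = generate_reference(plan)
        query, truth = mutate_genome(bundle, plan)
        u = truth.unique_insertions[0]
        novel = query[0].seq[u.query_start : u.query_end]
        ref = bundle.records[0].seq
        kmers = {ref[i:i+20] for i in range(len(ref) - 19)}
        assert all(novel[i:i+20] not in kmers for i in range(len(novel) - 19))


class TestFragmentAssembly:
    def test_no_breaks_one_contig_per_chromosome(self, small_pair):
        bundle, query, truth = small_pair
        plan = replace(bundle.plan, contig_break_policy="no-breaks")
        contigs, placements = fragment_assembly(query, truth, plan)
        assert len(contigs) == len(query)

    def test_break_and_drop_conservation(self):
        plan = SimulationPlan(seed=9, n_chromosomes=1, chromosome_length=120_000,
                              n_genes=5, transposon_counts={"Ty1": 3},
                              n_tandem_repeat_loci=0, snv_count=0, indel_count=0,
                              contig_break_policy="break-and-drop")
        bundle = generate_reference(plan)
        query, truth = mutate_genome(bundle, plan)
        contigs, placements = fragment_assembly(query, truth, plan)
        # >= 2 flanking contigs per retained locus
        assert len(contigs) >= 4
        qlen = sum(len(r.seq) for r in query)
        covered = sum(e - s for _, _, s, e in placements)
        withheld = 3 * plan.transposon_length
        assert covered + withheld == qlen

    def test_invalid_policy_rejected(self, small_plan):
        plan = replace(small_plan, contig_break_policy="shred")
        with pytest.raises(ValueError):
            plan.validate()


class TestSimulateDepth:
    def test_poisson_mean_within_three_se(self):
        plan = SimulationPlan(seed=10, n_chromosomes=1, chromosome_length=50_000,
                              n_genes=0, transposon_counts={}, n_tandem_repeat_loci=0)
        bundle = generate_reference(plan)
        mean = 50.0
        counts = np.concatenate([
            simulate_depth(bundle.records, mean, None, seed=s, window=5)[
                "chr1"
            ]
            for s in range(1)
        ])
        se = np.sqrt(mean / len(counts))
        assert abs(counts.mean() - mean) < 3 * se

    def test_deleted_region_windows_zero(self):
        plan = SimulationPlan(seed=11, n_chromosomes=1, chromosome_length=30_000,
                              n_genes=0, transposon_counts={}, n_tandem_repeat_loci=0)
        bundle = generate_reference(plan)
        cn = {"chr1": np.ones(30_000)}
        cn["chr1"][10_000:20_000] = 0.0
        d = simulate_depth(bundle.records, 400.0, None, seed=1, window=500, cn_track=cn)
        inside = d["chr1"][20:40]
        assert np.all(inside == 0)

    def test_same_seed_identical(self, small_bundle):
        a = simulate_depth(small_bundle.records, 100.0, gc_bias_profile(1.0), seed=3)
        b = simulate_depth(small_bundle.records, 100.0, gc_bias_profile(1.0), seed=3)
        assert all(np.array_equal(a[c], b[c]) for c in a)

    def test_nonpositive_mean_rejected(self, small_bundle):
        with pytest.raises(ValueError):
            simulate_depth(small_bundle.records, 0.0, None)
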