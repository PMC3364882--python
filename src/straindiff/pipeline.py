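"""End-to-end orchestration: align -> variants / assembly QC / CNV ->
presence -> compare / enrich, with a JSON run manifest.

Stages communicate only through serialized, documented formats inside the
output directory; rerunning with an identical config and seed reproduces
the outputs byte for byte (timestamps excluded from the manifest hash
inputs).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .align import AlignParams, align_to_reference, self_repeats, write_coords
from .assembly_qc import (
    classify_gaps,
    classify_transposons,
    gap_totals,
    tile_contigs,
    ty_family_copy_estimate,
)
from .cnv import call_segments, log2_ratio_track, segments_to_frame, window_counts, windows_to_frame
from .compare import distance_matrix, mosaic_to_frame, paint_mosaic, upgma
from .enrich import enrich_gene_list, results_to_frame
from .io import (
    parse_sequences,
    read_bed,
    read_bedgraph,
    read_gff3,
    write_bed,
    write_fasta,
    write_gff3,
    write_newick,
    write_vcf,
)
from .presence import gene_presence, mean_log2_per_gene, unique_regions, conservation_screen
from .simulate import (
    SimulationPlan,
    TransposonLocus,
    fragment_assembly,
    gc_bias_profile,
    generate_reference,
    mutate_genome,
    simulate_depth,
    simulate_panel,
)
from .variants import annotate_variants, call_variants, detect_tandem_repeats

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    Either give the input paths (reference/query FASTA, GFF3, transposon
    BED, depth bedGraphs, ...) or set ``simulate=True`` to generate a
    synthetic pair from ``plan`` first.
    """

    output_dir: str = "straindiff_out"
    seed: int = 0
    simulate: bool = False
    plan: SimulationPlan = field(default_factory=SimulationPlan)
    # real-data inputs (unused when simulate=True)
    reference_fasta: str | None = None
    query_fasta: str | None = None
    genes_gff: str | None = None
    transposon_bed: str | None = None
    depth_test_bedgraph: str | None = None
    depth_ref_bedgraph: str | None = None
    category_map: str | None = None
    # stage parameters
    align_params: AlignParams = field(default_factory=AlignParams)
    cnv_window: int = 414
    cnv_threshold: float = 0.6
    cnv_min_windows: int = 3
    presence_min_identity: float = 0.95
    presence_depth_cut: float = -0.6
    unique_min_length: int = 500
    mosaic_fragment: int = 1000
    panel_rates: dict = field(
        default_factory=lambda: {
            "lab": [0.002, 0.004],
            "industrial": [0.01, 0.02],
            "other": [0.03],
        }
    )
    run_compare: bool = True

    def validate(self):
        if not self.simulate:
            for name in ("reference_fasta", "query_fasta"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"config.{name} missing or not found: {p}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order and return the manifest dict."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "parameters": {
            "cnv_window": config.cnv_window,
            "cnv_threshold": config.cnv_threshold,
            "presence_min_identity": config.presence_min_identity,
            "presence_depth_cut": config.presence_depth_cut,
            "unique_min_length": config.unique_min_length,
            "mosaic_fragment": config.mosaic_fragment,
            "align_min_mem": config.align_params.min_mem,
        },
    }

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                counts = fn()
            except Exception as exc:  # pragma: no cover - error path
                (out / "PARTIAL_RESULTS").write_text(f"failed at stage {name}\n")
                raise PipelineError(name, exc) from exc
            dt = time.time() - t0
            manifest["stages"][name] = {"records": counts, "seconds": round(dt, 2)}
            logger.info("stage %-10s %8.2fs  %s", name, dt, counts)
            return counts

        return deco

    # ------------------------------------------------------------------ inputs
    truth = None
    panel = None
    if config.simulate:
        plan = config.plan
        plan.seed = config.seed
        bundle = generate_reference(plan)
        query, truth = mutate_genome(bundle, plan)
        contigs, _placements = fragment_assembly(query, truth, plan)
        cn = truth.copy_number_track(bundle.lengths)
        zm = truth.zero_coverage_mask(bundle.lengths)
        bias = gc_bias_profile(plan.bias_gc_slope)
        depth_test = simulate_depth(
            bundle.records, plan.depth_mean / plan.depth_window, bias,
            seed=config.seed, window=1, cn_track=cn, zero_mask=zm,
        )
        depth_ref = simulate_depth(
            bundle.records, plan.depth_mean / plan.depth_window, bias,
            seed=config.seed + 1, window=1,
        )
        genes, transposons = bundle.genes, bundle.transposons
        references = bundle.records
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        write_fasta(references, inputs / "reference.fasta")
        write_fasta(contigs, inputs / "contigs.fasta")
        write_gff3(genes, inputs / "genes.gff3")
        write_bed(
            [t.interval for t in transposons], inputs / "transposons.bed",
            extra_cols=lambda iv: _locus_cols(iv, transposons),
        )
        if config.run_compare:
            panel = simulate_panel(references, config.panel_rates, seed=config.seed)
        categories = None
    else:
        references = parse_sequences(config.reference_fasta)
        contigs = parse_sequences(config.query_fasta)
        genes = read_gff3(config.genes_gff) if config.genes_gff else []
        transposons = (
            _read_transposon_bed(config.transposon_bed) if config.transposon_bed else []
        )
        lengths = {r.id: len(r.seq) for r in references}
        depth_test = (
            read_bedgraph(config.depth_test_bedgraph, lengths)
            if config.depth_test_bedgraph
            else None
        )
        depth_ref = (
            read_bedgraph(config.depth_ref_bedgraph, lengths)
            if config.depth_ref_bedgraph
            else None
        )
        categories = config.category_map

    ref_seqs = {r.id: r.seq for r in references}
    contig_seqs = {c.id: c.seq for c in contigs}
    lengths = {r.id: len(r.seq) for r in references}

    # ------------------------------------------------------------------ align
    blocks = []

    @stage("align")
    def _align():
        nonlocal blocks
        blocks = align_to_reference(contigs, references, config.align_params)
        write_coords(blocks, out / "alignments.tsv")
        return len(blocks)

    # ------------------------------------------------------------------ variants
    calls, structural, annotations = [], [], []

    @stage("variants")
    def _variants():
        nonlocal calls, annotations
        repeats = detect_tandem_repeats(references, min_span_bp=8)
        calls = call_variants(blocks, contig_seqs, ref_seqs, structural_out=structural)
        annotations = annotate_variants(calls, genes, repeats, ref_seqs)
        write_vcf(calls, ref_seqs, out / "variants.vcf", annotations=annotations)
        write_bed(
            [r.interval for r in repeats], out / "tandem_repeats.bed",
            extra_cols=lambda iv: _repeat_cols(iv, repeats),
        )
        return {"snv": sum(1 for c in calls if c.kind == "snv"),
                "indel": sum(1 for c in calls if c.kind != "snv"),
                "structural": len(structural)}

    # ------------------------------------------------------------------ qc
    windows = []
    gaps, tcalls = [], []

    @stage("qc")
    def _qc():
        nonlocal gaps, tcalls
        placements, unplaced = tile_contigs(blocks)
        pd.DataFrame(
            {
                "contig": [p.contig_id for p in placements],
                "chr": [p.interval.seq_id for p in placements],
                "start": [p.interval.start for p in placements],
                "end": [p.interval.end for p in placements],
                "strand": [p.strand for p in placements],
                "score": [p.score for p in placements],
            }
        ).to_csv(out / "placements.tsv", sep="\t", index=False)
        reps = self_repeats(references)
        if depth_test is not None:
            gaps = classify_gaps(placements, depth_test, reps)
            pd.DataFrame(
                {
                    "chr": [g.interval.seq_id for g in gaps],
                    "start": [g.interval.start for g in gaps],
                    "end": [g.interval.end for g in gaps],
                    "zero_coverage": [g.has_zero_coverage_base for g in gaps],
                    "repeat": [g.overlaps_repeat for g in gaps],
                    "label": [g.label for g in gaps],
                }
            ).to_csv(out / "gaps.tsv", sep="\t", index=False)
        if transposons:
            tcalls = classify_transposons(transposons, placements, blocks)
            df = pd.DataFrame(
                {
                    "locus": [t.locus_id for t in tcalls],
                    "family": [t.family for t in tcalls],
                    "label": [t.label for t in tcalls],
                    "gap_bp": [t.gap_size for t in tcalls],
                }
            )
            if depth_test is not None and depth_ref is not None:
                est = ty_family_copy_estimate(transposons, depth_test, depth_ref)
                df["family_estimate"] = [
                    est.get(t.family, {}).get("estimate", "") for t in tcalls
                ]
            df.to_csv(out / "transposons.tsv", sep="\t", index=False)
        return {"placements": len(placements), "unplaced": len(unplaced),
                "gaps": gap_totals(gaps), "transposons": len(tcalls)}

    # ------------------------------------------------------------------ cnv
    segments = []

    @stage("cnv")
    def _cnv():
        nonlocal windows, segments
        if depth_test is None or depth_ref is None:
            return 0
        wt = window_counts(depth_test, config.cnv_window, lengths)
        wr = window_counts(depth_ref, config.cnv_window, lengths)
        windows = log2_ratio_track(wt, wr, config.cnv_window, lengths)
        segments = call_segments(
            windows, config.cnv_threshold, config.cnv_min_windows, genes
        )
        windows_to_frame(windows).to_csv(out / "cnv_windows.tsv", sep="\t", index=False)
        segments_to_frame(segments).to_csv(out / "cnv_segments.tsv", sep="\t", index=False)
        return {"windows": len(windows), "segments": len(segments)}

    # ------------------------------------------------------------------ presence
    presence_calls, uniques = [], []

    @stage("presence")
    def _presence():
        nonlocal presence_calls, uniques
        g_log2 = mean_log2_per_gene(genes, windows) if windows else {}
        presence_calls = gene_presence(
            genes, blocks, g_log2, config.presence_min_identity, config.presence_depth_cut
        )
        pd.DataFrame(
            {
                "gene": [p.gene_id for p in presence_calls],
                "best_identity": [p.best_identity for p in presence_calls],
                "mean_log2": [p.mean_log2 for p in presence_calls],
                "status": [p.status for p in presence_calls],
            }
        ).to_csv(out / "gene_presence.tsv", sep="\t", index=False)
        uniques = unique_regions(
            contigs, references, blocks, min_length=config.unique_min_length
        )
        if panel:
            flat = {sid: recs for grp in panel.values() for sid, recs in grp}
            if flat:
                conservation_screen(uniques, contigs, flat)
        write_bed([u.interval for u in uniques], out / "unique_regions.bed")
        return {
            "present": sum(1 for p in presence_calls if p.status == "present"),
            "absent_in_assembly": sum(
                1 for p in presence_calls if p.status == "absent_in_assembly"
            ),
            "deleted_high_confidence": sum(
                1 for p in presence_calls if p.status == "deleted_high_confidence"
            ),
            "unique_regions": len(uniques),
        }

    # ------------------------------------------------------------------ compare
    if panel:

        @stage("compare")
        def _compare():
            frags = paint_mosaic(references, panel, config.mosaic_fragment)
            mosaic_to_frame(frags).to_csv(out / "mosaic.tsv", sep="\t", index=False)
            genomes = [("query", [c for c in references])]
            for grp, strains in panel.items():
                genomes += [(sid, recs) for sid, recs in strains]
            dm = distance_matrix(genomes)
            dm.to_frame().to_csv(out / "distances.tsv", sep="\t")
            tree = upgma(dm)
            write_newick(tree.newick, out / "phylogeny.nwk")
            return {"fragments": len(frags), "taxa": len(dm.ids)}

    # ------------------------------------------------------------------ enrich
    if categories:

        @stage("enrich")
        def _enrich():
            from .enrich import read_category_map

            cat = read_category_map(categories)
            ann_by_id = {a.variant_id: a for a in annotations}
            snv_genes = sorted(
                {
                    a.gene_id
                    for c in calls
                    if c.kind == "snv"
                    for a in [ann_by_id.get(c.variant_id)]
                    if a and a.gene_id and a.effect == "missense"
                }
            )
            results = enrich_gene_list([g for g in snv_genes if g in cat], cat)
            results_to_frame(results).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            return len(results)

    manifest["truth_available"] = truth is not None
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _locus_cols(iv, transposons):
    for t in transposons:
        if t.interval == iv:
            return [t.locus_id, t.family, t.ltr_length]
    return []


def _repeat_cols(iv, repeats):
    for r in repeats:
        if r.interval == iv:
            return [r.unit, f"{r.copies:.2f}"]
    return []


def _read_transposon_bed(path):
    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            p = line.rstrip("\n").split("\t")
            from .io import GenomicInterval

            loci.append(
                TransposonLocus(
                    locus_id=p[3] if len(p) > 3 else f"locus{len(loci)+1}",
                    family=p[4] if len(p) > 4 else "Ty1",
                    interval=GenomicInterval(p[0], int(p[1]), int(p[2])),
                    ltr_length=int(p[5]) if len(p) > 5 else 300,
                )
            )
    return loci
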