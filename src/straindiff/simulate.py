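"""Synthetic reference/query genome pairs with planted variation and depth.

The generator emulates a compact yeast-like genome: a few chromosomes with
LTR-flanked retrotransposons (families Ty1..Ty5, ~6 kb elements with ~300 bp
terminal repeats identical within a family), perfect tandem-repeat arrays,
and protein-coding genes (ATG + stop-free codons + stop), with gene blocks
near chromosome ends marking subtelomeric regions.

A derived query genome carries planted SNVs, 1-90 bp indels (enriched in
tandem repeats with unit-multiple lengths), large deletions, segmental
duplications, transposon excisions that leave a solo LTR, and novel unique
insertions. The query is then fragmented into contigs that break at
repeats, and Poisson read-depth tracks with a shared GC bias are simulated
for both strains so the depth *ratio* cancels the bias.

Every operation is a pure function of (inputs, seed); each draws from its
own derived substream so stages can be regenerated independently.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np

from .io import GenomicInterval, SequenceRecord, revcomp

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


class PlacementError(ValueError):
    """Feature demand exceeds chromosome capacity."""


class PlanConflictError(ValueError):
    """Planted edits collide; message lists the collisions."""


@dataclass
class SimulationPlan:
    """All knobs for one simulated genome pair.

    Defaults are a desk-scale rendition of a laboratory yeast strain pair:
    ~0.2% SNV divergence, indels averaging ~3 bp and enriched in tandem
    repeats, ~6 kb LTR transposons, and ~50x sequencing depth
    (414 reads per 414 bp window).
    """

    seed: int = 0
    # reference layout
    n_chromosomes: int = 2
    chromosome_length: int = 250_000
    gc_content: float = 0.38
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (300, 1500)
    subtelomere_length: int = 15_000
    subtelomeric_gene_fraction: float = 0.15
    transposon_counts: dict = field(
        default_factory=lambda: {"Ty1": 3, "Ty2": 2, "Ty3": 1, "Ty4": 1, "Ty5": 1}
    )
    transposon_length: int = 6000
    ltr_length: int = 300
    transposon_divergence: float = 0.01
    n_tandem_repeat_loci: int = 40
    tandem_unit_range: tuple[int, int] = (3, 60)
    tandem_copies_range: tuple[int, int] = (5, 40)
    # planted variation
    snv_count: int | None = 1000
    snv_rate: float | None = None
    indel_count: int = 130
    indel_tandem_fraction: float = 0.6
    indel_max: int = 90
    indel_geom_p: float = 0.35
    large_deletion_specs: list = field(default_factory=list)  # (length, subtelomeric)
    duplication_specs: list = field(default_factory=list)  # (length, extra_copies)
    excised_transposon_count: int = 0
    excised_loci: list = field(default_factory=list)  # explicit locus ids
    unique_insertion_specs: list = field(default_factory=list)  # lengths
    # assembly fragmentation
    contig_break_policy: str = "break"  # no-breaks | break | break-and-drop
    locus_policies: dict = field(default_factory=dict)  # per-locus override
    random_break_rate: float = 0.0
    min_contig_length: int = 200
    assembly_dropout_genes: int = 0  # genes withheld from contigs (depth normal)
    zero_coverage_specs: list = field(default_factory=list)  # lengths, no reads
    # depth
    depth_mean: float = 414.0  # reads per window (~50x at 50 bp reads)
    depth_window: int = 414
    bias_gc_slope: float = 1.0

    @classmethod
    def scaled(cls, seed: int = 0, n_chromosomes: int = 2,
               chromosome_length: int = 250_000, **overrides) -> "SimulationPlan":
        """A plan with yeast-like feature densities scaled to the genome
        size (genes ~1/2.5 kb, transposons ~4/Mb, SNVs ~0.2%, indels ~0.025%)."""
        g = n_chromosomes * chromosome_length
        n_ty = max(1, round(g * 4e-6))
        counts = {}
        for i, fam in enumerate(["Ty1", "Ty2", "Ty3", "Ty4", "Ty5"]):
            share = max(0, n_ty // 5 + (1 if i < n_ty % 5 else 0))
            if share:
                counts[fam] = share
        plan = cls(
            seed=seed,
            n_chromosomes=n_chromosomes,
            chromosome_length=chromosome_length,
            n_genes=max(4, g // 3000),
            transposon_counts=counts,
            n_tandem_repeat_loci=max(2, g // 12_500),
            snv_count=max(10, round(g * 0.002)),
            indel_count=max(2, round(g * 0.00025)),
        )
        for k, v in overrides.items():
            setattr(plan, k, v)
        return plan

    def validate(self):
        if self.n_chromosomes <= 0 or self.chromosome_length <= 0:
            raise ValueError("need at least one non-empty chromosome")
        if self.transposon_length <= 0 or self.ltr_length <= 0:
            raise ValueError("transposon_length and ltr_length must be > 0")
        if self.transposon_length <= 2 * self.ltr_length:
            raise ValueError("transposon body must be longer than its two LTRs")
        for r in (self.snv_rate, self.indel_tandem_fraction, self.gc_content):
            if r is not None and not (0.0 <= r <= 1.0):
                raise ValueError(f"rate {r} outside [0,1]")
        for c in (
            self.n_genes,
            self.indel_count,
            self.excised_transposon_count,
            self.n_tandem_repeat_loci,
        ):
            if c < 0:
                raise ValueError("counts must be >= 0")
        if self.contig_break_policy not in ("no-breaks", "break", "break-and-drop"):
            raise ValueError(f"unknown contig_break_policy {self.contig_break_policy!r}")


def _rng(plan_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([plan_seed & 0x7FFFFFFF, stream]))


def _random_seq(rng, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


# ---------------------------------------------------------------------------
# Feature records


@dataclass(frozen=True)
class TransposonLocus:
    locus_id: str
    family: str
    interval: GenomicInterval
    ltr_length: int


@dataclass(frozen=True)
class TandemLocus:
    interval: GenomicInterval
    unit: int
    copies: int


@dataclass
class ReferenceBundle:
    """generate_reference output: sequences plus feature annotation."""

    records: list[SequenceRecord]
    genes: list  # GeneModel
    transposons: list[TransposonLocus]
    tandems: list[TandemLocus]
    plan: SimulationPlan

    @property
    def seqs(self) -> dict[str, str]:
        return {r.id: r.seq for r in self.records}

    @property
    def lengths(self) -> dict[str, int]:
        return {r.id: len(r.seq) for r in self.records}


# ---------------------------------------------------------------------------
# Truth records


@dataclass(frozen=True)
class SnvTruth:
    chrom: str
    ref_pos: int
    ref: str
    alt: str
    query_pos: int = -1


@dataclass(frozen=True)
class IndelTruth:
    kind: str  # insertion | deletion
    chrom: str
    ref_pos: int
    length: int
    seq: str
    in_tandem: bool
    query_pos: int = -1


@dataclass(frozen=True)
class RegionTruth:
    chrom: str
    ref_start: int
    ref_end: int
    genes: tuple = ()
    subtelomeric: bool = False
    query_start: int = -1
    query_end: int = -1
    query_chrom: str = ""  # chromosome of the query interval (may differ for duplications)


@dataclass
class TruthTable:
    """Ground truth for all planted edits, in reference and query coordinates."""

    snvs: list[SnvTruth] = field(default_factory=list)
    indels: list[IndelTruth] = field(default_factory=list)
    deletions: list[RegionTruth] = field(default_factory=list)
    duplications: list[RegionTruth] = field(default_factory=list)  # source; query_* = copy
    transposon_states: dict = field(default_factory=dict)  # locus_id -> retained|excised
    transposon_query_intervals: dict = field(default_factory=dict)  # locus_id -> (chrom, qs, qe)
    unique_insertions: list[RegionTruth] = field(default_factory=list)  # query_* only
    zero_coverage: list[RegionTruth] = field(default_factory=list)
    assembly_dropouts: list[RegionTruth] = field(default_factory=list)
    contig_placements: list = field(default_factory=list)  # (contig_id, chrom, qs, qe)

    def copy_number_track(self, lengths: dict[str, int]) -> dict[str, np.ndarray]:
        """Per-base expected copy number of the query strain on reference
        coordinates (deletions/excisions -> 0, duplication sources -> 1+extra)."""
        cn = {c: np.ones(n) for c, n in lengths.items()}
        for d in self.deletions:
            cn[d.chrom][d.ref_start : d.ref_end] = 0.0
        for locus_id, state in self.transposon_states.items():
            if state == "excised":
                c, s, e = self._excised_ref[locus_id]
                cn[c][s:e] = 0.0
        for d in self.duplications:
            extra = self._dup_extra.get((d.chrom, d.ref_start, d.ref_end), 1)
            cn[d.chrom][d.ref_start : d.ref_end] += extra
        return cn

    _excised_ref: dict = field(default_factory=dict)  # locus_id -> (chrom, s, e) deleted part
    _dup_extra: dict = field(default_factory=dict)

    def length_delta(self) -> int:
        """Net query-minus-reference length implied by the planted edits."""
        delta = 0
        for s in self.indels:
            delta += s.length if s.kind == "insertion" else -s.length
        for d in self.deletions:
            delta -= d.ref_end - d.ref_start
        for _, (c, s, e) in self._excised_ref.items():
            delta -= e - s
        for d in self.duplications:
            delta += (d.ref_end - d.ref_start) * self._dup_extra.get(
                (d.chrom, d.ref_start, d.ref_end), 1
            )
        for u in self.unique_insertions:
            delta += u.query_end - u.query_start
        return delta

    def zero_coverage_mask(self, lengths: dict[str, int]) -> dict[str, np.ndarray]:
        mask = {c: np.ones(n) for c, n in lengths.items()}
        for z in self.zero_coverage:
            mask[z.chrom][z.ref_start : z.ref_end] = 0.0
        return mask


# ---------------------------------------------------------------------------
# Reference generation


class _Occupancy:
    """Per-chromosome reserved intervals with padding, for collision-free
    feature placement."""

    def __init__(self, lengths: dict[str, int]):
        self.iv: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
        self.lengths = lengths

    def free(self, chrom: str, start: int, end: int) -> bool:
        if start < 0 or end > self.lengths[chrom]:
            return False
        for s, e in self.iv[chrom]:
            if start < e and s < end:
                return False
        return True

    def reserve(self, chrom: str, start: int, end: int):
        self.iv[chrom].append((start, end))

    def place(self, rng, chrom: str, length: int, pad: int, lo=None, hi=None, tries=300):
        L = self.lengths[chrom]
        lo = 0 if lo is None else lo
        hi = L if hi is None else hi
        if hi - lo < length:
            raise PlacementError(f"no room for a {length} bp feature on {chrom}")
        for _ in range(tries):
            s = int(rng.integers(lo, hi - length + 1))
            if self.free(chrom, s - pad, s + length + pad):
                self.reserve(chrom, s - pad, s + length + pad)
                return s
        raise PlacementError(
            f"could not place a {length} bp feature on {chrom} after {tries} tries"
        )


def _gene_sequence(rng, n_codons: int) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in _STOPS and not (len(codons) == 0):
            codons.append(c)
    codons.append(rng.choice(["TAA", "TAG", "TGA"]))
    return "".join(codons)


def generate_reference(plan: SimulationPlan) -> ReferenceBundle:
    """Build the reference genome with transposons, tandem arrays and genes.

    Deterministic in plan.seed. Transposon copies of one family share
    byte-identical LTRs; bodies diverge by ``transposon_divergence``.
    """
    from .io import GeneModel

    plan.validate()
    rng = _rng(plan.seed, 1)
    lengths = {f"chr{i+1}": plan.chromosome_length for i in range(plan.n_chromosomes)}
    chrom_ids = list(lengths)
    seqs = {c: list(_random_seq(rng, plan.chromosome_length, plan.gc_content)) for c in chrom_ids}
    occ = _Occupancy(lengths)

    # family prototype sequences (shared LTR, per-copy diverged body)
    body_len = plan.transposon_length - 2 * plan.ltr_length
    families = {}
    for fam in plan.transposon_counts:
        families[fam] = (
            _random_seq(rng, plan.ltr_length, 0.45),
            _random_seq(rng, body_len, 0.45),
        )

    transposons: list[TransposonLocus] = []
    for fam, count in plan.transposon_counts.items():
        ltr, body = families[fam]
        for i in range(count):
            chrom = chrom_ids[int(rng.integers(0, len(chrom_ids)))]
            s = occ.place(rng, chrom, plan.transposon_length, pad=150)
            b = list(body)
            n_mut = int(round(plan.transposon_divergence * body_len))
            for p in rng.choice(body_len, size=n_mut, replace=False):
                b[p] = rng.choice([x for x in "ACGT" if x != b[p]])
            element = ltr + "".join(b) + ltr
            seqs[chrom][s : s + plan.transposon_length] = list(element)
            transposons.append(
                TransposonLocus(
                    locus_id=f"{fam}-{i+1}",
                    family=fam,
                    interval=GenomicInterval(chrom, s, s + plan.transposon_length),
                    ltr_length=plan.ltr_length,
                )
            )

    tandems: list[TandemLocus] = []
    for _ in range(plan.n_tandem_repeat_loci):
        unit = int(rng.integers(plan.tandem_unit_range[0], plan.tandem_unit_range[1] + 1))
        copies = int(
            rng.integers(plan.tandem_copies_range[0], plan.tandem_copies_range[1] + 1)
        )
        span = unit * copies
        chrom = chrom_ids[int(rng.integers(0, len(chrom_ids)))]
        s = occ.place(rng, chrom, span, pad=60)
        u = _random_seq(rng, unit, 0.5)
        seqs[chrom][s : s + span] = list(u * copies)
        tandems.append(TandemLocus(GenomicInterval(chrom, s, s + span), unit, copies))

    genes: list[GeneModel] = []
    n_sub = int(round(plan.n_genes * plan.subtelomeric_gene_fraction))
    for gi in range(plan.n_genes):
        glen = int(rng.integers(plan.gene_length_range[0], plan.gene_length_range[1] + 1))
        glen -= glen % 3
        chrom = chrom_ids[int(rng.integers(0, len(chrom_ids)))]
        subtel = min(plan.subtelomere_length, lengths[chrom] // 8)
        if gi < n_sub:
            # subtelomeric block: near either chromosome end
            if rng.random() < 0.5:
                zones = [(0, subtel), (lengths[chrom] - subtel, lengths[chrom])]
            else:
                zones = [(lengths[chrom] - subtel, lengths[chrom]), (0, subtel)]
        else:
            zones = [(subtel, lengths[chrom] - subtel)]
        zones.append((0, lengths[chrom]))  # last resort: anywhere free
        for zi, (lo, hi) in enumerate(zones):
            try:
                s = occ.place(rng, chrom, glen, pad=30, lo=lo, hi=hi)
                break
            except PlacementError:
                if zi == len(zones) - 1:
                    raise
        strand = "+" if rng.random() < 0.5 else "-"
        cds = _gene_sequence(rng, glen // 3)
        seqs[chrom][s : s + glen] = list(cds if strand == "+" else revcomp(cds))
        iv = GenomicInterval(chrom, s, s + glen, strand)
        genes.append(GeneModel(f"G{gi+1:04d}", iv, [iv], strand))

    records = [SequenceRecord(c, "".join(seqs[c])) for c in chrom_ids]
    genes.sort(key=lambda g: (g.interval.seq_id, g.interval.start))
    transposons.sort(key=lambda t: (t.interval.seq_id, t.interval.start))
    tandems.sort(key=lambda t: (t.interval.seq_id, t.interval.start))
    return ReferenceBundle(records, genes, transposons, tandems, plan)


# ---------------------------------------------------------------------------
# Mutation


@dataclass(frozen=True)
class _Edit:
    chrom: str
    start: int
    end: int  # ref interval replaced (start==end for pure insertion)
    replacement: str
    kind: str
    meta: tuple = ()


class RefQueryMap:
    """Piecewise-affine reference->query coordinate map for one chromosome."""

    def __init__(self, ref_breaks: list[int], query_breaks: list[int]):
        self.rb = ref_breaks
        self.qb = query_breaks

    def to_query(self, pos: int) -> int:
        i = bisect.bisect_right(self.rb, pos) - 1
        return self.qb[i] + (pos - self.rb[i])


def _eligible_positions_mask(bundle: ReferenceBundle) -> dict[str, np.ndarray]:
    """Positions where point edits may be planted: outside transposons
    (padded) and tandem arrays (padded), so recovery is unambiguous."""
    mask = {c: np.ones(n, dtype=bool) for c, n in bundle.lengths.items()}
    for t in bundle.transposons:
        iv = t.interval
        mask[iv.seq_id][max(0, iv.start - 50) : iv.end + 50] = False
    for t in bundle.tandems:
        iv = t.interval
        mask[iv.seq_id][max(0, iv.start - 10) : iv.end + 10] = False
    for c in mask:  # keep clear of chromosome ends (seeding needs flanks)
        mask[c][:100] = False
        mask[c][-100:] = False
    return mask


def mutate_genome(bundle: ReferenceBundle, plan: SimulationPlan | None = None):
    """Apply the planted variation plan to the reference.

    Returns (query records, TruthTable). Raises PlanConflictError when two
    planted edits would overlap.
    """
    plan = plan or bundle.plan
    plan.validate()
    rng = _rng(plan.seed, 2)
    seqs = bundle.seqs
    lengths = bundle.lengths
    truth = TruthTable()
    edits: list[_Edit] = []
    reserved = _Occupancy(lengths)
    # features are off-limits for structural edits unless the edit targets them
    for t in bundle.transposons:
        reserved.reserve(t.interval.seq_id, t.interval.start - 100, t.interval.end + 100)

    def reserve_edit(e: _Edit, pad=5):
        reserved.reserve(e.chrom, min(e.start, e.start) - pad, max(e.end, e.start + 1) + pad)
        edits.append(e)

    # --- transposon excisions: delete element minus one terminal repeat
    excised = list(plan.excised_loci)
    if plan.excised_transposon_count and not excised:
        pool = [t.locus_id for t in bundle.transposons]
        if plan.excised_transposon_count > len(pool):
            raise PlacementError("more excisions requested than transposon loci")
        excised = [
            pool[i]
            for i in sorted(
                rng.choice(len(pool), size=plan.excised_transposon_count, replace=False)
            )
        ]
    by_id = {t.locus_id: t for t in bundle.transposons}
    for locus_id in excised:
        t = by_id[locus_id]
        iv = t.interval
        s, e = iv.start + t.ltr_length, iv.end
        edits.append(_Edit(iv.seq_id, s, e, "", "excision", (locus_id,)))
        truth._excised_ref[locus_id] = (iv.seq_id, s, e)
    for t in bundle.transposons:
        truth.transposon_states[t.locus_id] = (
            "excised" if t.locus_id in excised else "retained"
        )

    gene_tree = sorted(
        ((g.interval.seq_id, g.interval.start, g.interval.end, g.gene_id) for g in bundle.genes)
    )

    def genes_in(chrom, s, e):
        return tuple(g[3] for g in gene_tree if g[0] == chrom and g[1] >= s and g[2] <= e)

    chrom_ids = list(lengths)

    # --- large deletions
    for length, subtel in plan.large_deletion_specs:
        chrom = chrom_ids[int(rng.integers(0, len(chrom_ids)))]
        zone = min(plan.subtelomere_length, lengths[chrom] // 4)
        if subtel:
            side = rng.random() < 0.5
            lo, hi = (
                (200, zone)
                if side
                else (lengths[chrom] - zone, lengths[chrom] - 200)
            )
        else:
            lo, hi = zone, lengths[chrom] - zone
        # deletion boundaries must not bisect a gene: a half-deleted gene
        # is legitimately called deleted but is ambiguous as ground truth
        for _try in range(300):
            s = reserved.place(rng, chrom, length, pad=120, lo=lo, hi=hi)
            bisected = any(
                g[0] == chrom and g[1] < e_ and s < g[2] and not (g[1] >= s and g[2] <= e_)
                for g in gene_tree
                for e_ in (s + length,)
            )
            if not bisected:
                break
            reserved.iv[chrom].pop()
        else:
            raise PlacementError("could not place a large deletion off gene boundaries")
        edits.append(_Edit(chrom, s, s + length, "", "deletion", (subtel,)))
        truth.deletions.append(
            RegionTruth(chrom, s, s + length, genes_in(chrom, s, s + length), subtel)
        )

    # --- duplications: insert extra copies of a gene-bearing source window
    for length, extra in plan.duplication_specs:
        for _try in range(300):
            chrom = chrom_ids[int(rng.integers(0, len(chrom_ids)))]
            lo, hi = 200, lengths[chrom] - 200
            s = int(rng.integers(lo, hi - length))
            if reserved.free(chrom, s - 120, s + length + 120) and genes_in(
                chrom, s, s + length
            ):
                break
        else:
            # fall back to any free window
            chrom = chrom_ids[int(rng.integers(0, len(chrom_ids)))]
            s = reserved.place(rng, chrom, length, pad=120)
            reserved.iv[chrom].pop()
        reserved.reserve(chrom, s - 120, s + length + 120)
        source_seq = seqs[chrom][s : s + length]
        tgt_chrom = chrom_ids[int(rng.integers(0, len(chrom_ids)))]
        for _ in range(int(extra)):
            tp = reserved.place(rng, tgt_chrom, 1, pad=120)
            edits.append(
                _Edit(tgt_chrom, tp, tp, source_seq, "duplication", (chrom, s, s + length))
            )
        truth.duplications.append(
            RegionTruth(chrom, s, s + length, genes_in(chrom, s, s + length))
        )
        truth._dup_extra[(chrom, s, s + length)] = int(extra)

    # --- unique insertions: novel sequence, no 20-mer shared with the reference
    ref_kmers = set()
    k = 20
    for c in chrom_ids:
        s = seqs[c]
        ref_kmers.update(s[i : i + k] for i in range(0, len(s) - k + 1, 1))
    for length in plan.unique_insertion_specs:
        for _try in range(50):
            novel = _random_seq(rng, length, 0.5)
            if all(novel[i : i + k] not in ref_kmers for i in range(length - k + 1)):
                break
        else:
            raise PlacementError("could not draw a unique insertion sequence")
        chrom = chrom_ids[int(rng.integers(0, len(chrom_ids)))]
        tp = reserved.place(rng, chrom, 1, pad=120)
        edits.append(_Edit(chrom, tp, tp, novel, "unique_insertion", (length,)))

    # --- zero-coverage (unsequenceable) regions
    for length in plan.zero_coverage_specs:
        chrom = chrom_ids[int(rng.integers(0, len(chrom_ids)))]
        s = reserved.place(rng, chrom, length, pad=150)
        truth.zero_coverage.append(RegionTruth(chrom, s, s + length))

    # --- assembly dropouts: untouched genes later withheld from contigs
    if plan.assembly_dropout_genes:
        candidates = [
            g
            for g in bundle.genes
            if reserved.free(
                g.interval.seq_id, g.interval.start - 150, g.interval.end + 150
            )
        ]
        if len(candidates) < plan.assembly_dropout_genes:
            raise PlacementError("not enough untouched genes for assembly dropouts")
        picks = rng.choice(len(candidates), size=plan.assembly_dropout_genes, replace=False)
        for pi in sorted(picks):
            g = candidates[pi]
            iv = g.interval
            s, e = iv.start - 100, iv.end + 100
            reserved.reserve(iv.seq_id, s - 50, e + 50)
            truth.assembly_dropouts.append(
                RegionTruth(iv.seq_id, s, e, (g.gene_id,))
            )

    # --- small indels
    tandem_pool = [t for t in bundle.tandems if t.unit <= plan.indel_max]
    n_tandem = int(round(plan.indel_count * plan.indel_tandem_fraction))
    n_tandem = min(n_tandem, len(tandem_pool))
    used_tandems = (
        rng.choice(len(tandem_pool), size=n_tandem, replace=False) if n_tandem else []
    )
    for ti in sorted(used_tandems):
        t = tandem_pool[ti]
        iv = t.interval
        max_units = min((t.copies - 2), plan.indel_max // t.unit)
        if max_units < 1:
            continue
        m = int(rng.integers(1, max_units + 1))
        length = m * t.unit
        unit_seq = seqs[iv.seq_id][iv.start : iv.start + t.unit]
        at = iv.start + t.unit * int(rng.integers(1, t.copies - (m if True else 0)))
        if rng.random() < 0.5 and at + length <= iv.end:
            e = _Edit(iv.seq_id, at, at + length, "", "indel_del", (True,))
        else:
            e = _Edit(iv.seq_id, at, at, unit_seq * m, "indel_ins", (True,))
        if not reserved.free(iv.seq_id, e.start - 5, max(e.end, e.start + 1) + 5):
            continue
        reserve_edit(e)

    mask = _eligible_positions_mask(bundle)
    n_free_indels = plan.indel_count - sum(1 for e in edits if e.kind.startswith("indel"))
    for _ in range(max(0, n_free_indels)):
        length = min(plan.indel_max, 1 + int(rng.geometric(plan.indel_geom_p)))
        for _try in range(300):
            chrom = chrom_ids[int(rng.integers(0, len(chrom_ids)))]
            p = int(rng.integers(100, lengths[chrom] - 100))
            if mask[chrom][max(0, p - 5) : p + length + 5].all() and reserved.free(
                chrom, p - 5, p + length + 5
            ):
                break
        else:
            raise PlacementError("no room left for planted indels")
        if rng.random() < 0.5:
            reserve_edit(_Edit(chrom, p, p + length, "", "indel_del", (False,)))
        else:
            reserve_edit(_Edit(chrom, p, p, _random_seq(rng, length), "indel_ins", (False,)))

    # --- SNVs
    if plan.snv_count is not None:
        n_snv = plan.snv_count
    elif plan.snv_rate:
        n_eligible = sum(int(m.sum()) for m in mask.values())
        n_snv = int(rng.binomial(n_eligible, plan.snv_rate))
    else:
        n_snv = 0
    placed = 0
    guard = 0
    while placed < n_snv:
        guard += 1
        if guard > 50 * max(1, n_snv):
            raise PlacementError("SNV demand exceeds eligible positions")
        chrom = chrom_ids[int(rng.integers(0, len(chrom_ids)))]
        p = int(rng.integers(0, lengths[chrom]))
        if not mask[chrom][p] or not reserved.free(chrom, p - 2, p + 3):
            continue
        ref_base = seqs[chrom][p]
        if ref_base == "N":
            continue
        alt = rng.choice([b for b in "ACGT" if b != ref_base])
        reserve_edit(_Edit(chrom, p, p + 1, alt, "snv"), pad=2)
        placed += 1

    # --- conflict check and application
    by_chrom: dict[str, list[_Edit]] = {c: [] for c in chrom_ids}
    for e in edits:
        by_chrom[e.chrom].append(e)
    collisions = []
    for c, ce in by_chrom.items():
        ce.sort(key=lambda e: (e.start, e.end))
        for a, b in zip(ce, ce[1:]):
            if b.start < a.end:
                collisions.append((a, b))
    if collisions:
        raise PlanConflictError(f"{len(collisions)} colliding edits: {collisions[:5]}")

    query_records = []
    maps: dict[str, RefQueryMap] = {}
    snvs, indels = [], []
    for c in chrom_ids:
        src = seqs[c]
        parts = []
        rb, qb = [0], [0]
        rpos = qpos = 0
        for e in by_chrom[c]:
            parts.append(src[rpos : e.start])
            qpos += e.start - rpos
            q_at = qpos
            parts.append(e.replacement)
            qpos += len(e.replacement)
            rpos = e.end
            rb.append(rpos)
            qb.append(qpos)
            if e.kind == "snv":
                snvs.append(SnvTruth(c, e.start, src[e.start], e.replacement, q_at))
            elif e.kind == "indel_del":
                indels.append(
                    IndelTruth("deletion", c, e.start, e.end - e.start,
                               src[e.start : e.end], e.meta[0], q_at)
                )
            elif e.kind == "indel_ins":
                indels.append(
                    IndelTruth("insertion", c, e.start, len(e.replacement),
                               e.replacement, e.meta[0], q_at)
                )
            elif e.kind == "duplication":
                src_key = e.meta
                truth.duplications = [
                    replace(d, query_start=q_at, query_end=q_at + len(e.replacement),
                            query_chrom=c)
                    if (d.chrom, d.ref_start, d.ref_end) == src_key
                    and d.query_start < 0
                    else d
                    for d in truth.duplications
                ]
                # note: with multiple extra copies the first copy's query
                # interval is recorded; all copies are in _dup_extra
            elif e.kind == "unique_insertion":
                truth.unique_insertions.append(
                    RegionTruth(c, -1, -1, (), False, q_at, q_at + len(e.replacement), c)
                )
        parts.append(src[rpos:])
        query_records.append(SequenceRecord(c, "".join(parts)))
        maps[c] = RefQueryMap(rb, qb)

    truth.snvs = sorted(snvs, key=lambda s: (s.chrom, s.ref_pos))
    truth.indels = sorted(indels, key=lambda s: (s.chrom, s.ref_pos))

    # map feature/region coordinates into the query
    for t in bundle.transposons:
        iv = t.interval
        m = maps[iv.seq_id]
        if truth.transposon_states[t.locus_id] == "retained":
            truth.transposon_query_intervals[t.locus_id] = (
                iv.seq_id, m.to_query(iv.start), m.to_query(iv.end)
            )
        else:  # solo LTR remnant
            truth.transposon_query_intervals[t.locus_id] = (
                iv.seq_id, m.to_query(iv.start), m.to_query(iv.start) + t.ltr_length
            )
    truth.zero_coverage = [
        replace(z, query_start=maps[z.chrom].to_query(z.ref_start),
                query_end=maps[z.chrom].to_query(z.ref_end))
        for z in truth.zero_coverage
    ]
    truth.assembly_dropouts = [
        replace(z, query_start=maps[z.chrom].to_query(z.ref_start),
                query_end=maps[z.chrom].to_query(z.ref_end))
        for z in truth.assembly_dropouts
    ]
    truth.deletions = [
        replace(d, query_start=maps[d.chrom].to_query(d.ref_start),
                query_end=maps[d.chrom].to_query(d.ref_start))
        for d in truth.deletions
    ]
    return query_records, truth


# ---------------------------------------------------------------------------
# Fragmentation


def fragment_assembly(
    query_records: list[SequenceRecord],
    truth: TruthTable,
    plan: SimulationPlan,
):
    """Break the query genome into contigs.

    Contigs break at every retained transposon locus under policy "break" or
    "break-and-drop" (the latter also withholds the element interior,
    creating contig-break evidence); zero-coverage regions and assembly
    dropouts are always withheld. Placements tile the query except withheld
    intervals. Returns (contigs, placements); placements are also recorded
    on the truth table.
    """
    rng = _rng(plan.seed, 3)
    breaks: dict[str, set[int]] = {r.id: set() for r in query_records}
    withheld: dict[str, list[tuple[int, int]]] = {r.id: [] for r in query_records}

    for locus_id, state in truth.transposon_states.items():
        if state != "retained":
            continue
        chrom, qs, qe = truth.transposon_query_intervals[locus_id]
        policy = plan.locus_policies.get(locus_id, plan.contig_break_policy)
        if policy in ("break", "break-and-drop"):
            breaks[chrom].update((qs, qe))
        if policy == "break-and-drop":
            withheld[chrom].append((qs, qe))
    for z in truth.zero_coverage + truth.assembly_dropouts:
        breaks[z.chrom].update((z.query_start, z.query_end))
        withheld[z.chrom].append((z.query_start, z.query_end))
    if plan.random_break_rate:
        for r in query_records:
            n = rng.poisson(plan.random_break_rate * len(r.seq))
            breaks[r.id].update(int(x) for x in rng.integers(0, len(r.seq), size=n))

    contigs: list[SequenceRecord] = []
    placements: list[tuple[str, str, int, int]] = []
    ci = 0
    for r in query_records:
        wh = sorted(withheld[r.id])
        pts = sorted(set([0, len(r.seq)]) | breaks[r.id])
        for s, e in zip(pts, pts[1:]):
            drop = any(ws <= s and e <= we for ws, we in wh)
            if drop or e - s < plan.min_contig_length:
                continue
            ci += 1
            cid = f"contig{ci:04d}"
            contigs.append(SequenceRecord(cid, r.seq[s:e]))
            placements.append((cid, r.id, s, e))
    truth.contig_placements = placements
    return contigs, placements


# ---------------------------------------------------------------------------
# Depth simulation


def gc_bias_profile(slope: float = 1.0, baseline_gc: float = 0.40):
    """Deterministic multiplicative bias as a function of window GC content."""

    def bias(gc: np.ndarray) -> np.ndarray:
        return np.clip(1.0 + slope * (gc - baseline_gc), 0.05, None)

    return bias


def simulate_depth(
    records: list[SequenceRecord],
    coverage_mean: float,
    bias_profile=None,
    seed: int = 0,
    window: int = 414,
    cn_track: dict[str, np.ndarray] | None = None,
    zero_mask: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Per-window Poisson read counts on the given genome.

    ``coverage_mean`` is the expected reads per full window for copy number
    1 and bias 1. Bias is a deterministic function of window GC content, so
    two strains simulated on the same genome share it exactly and it cancels
    in the depth ratio. ``cn_track``/``zero_mask`` are per-base multipliers
    (planted duplications double the rate, deletions zero it).
    """
    if coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    if window < 1:
        raise ValueError("window must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 4]))
    bias_fn = bias_profile or (lambda gc: np.ones_like(gc))
    out: dict[str, np.ndarray] = {}
    for r in records:
        arr = np.frombuffer(r.seq.encode(), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        n = len(arr)
        n_win = (n + window - 1) // window
        rate = np.full(n, coverage_mean / window)
        if cn_track is not None:
            rate = rate * cn_track[r.id][:n]
        if zero_mask is not None:
            rate = rate * zero_mask[r.id][:n]
        pad = n_win * window - n
        gc_w = np.pad(is_gc.astype(float), (0, pad)).reshape(n_win, window)
        widths = np.minimum(window, n - np.arange(n_win) * window)
        gc_frac = gc_w.sum(axis=1) / widths
        lam = np.pad(rate, (0, pad)).reshape(n_win, window).sum(axis=1) * bias_fn(gc_frac)
        out[r.id] = rng.poisson(lam).astype(float)
    return out


def simulate_panel(
    reference: list[SequenceRecord],
    groups: dict[str, list[float]],
    seed: int = 0,
) -> dict[str, list[tuple[str, list[SequenceRecord]]]]:
    """Derive a panel of strain genomes from one ancestor.

    ``groups`` maps a group label to a list of per-strain SNV divergence
    rates. Returns {group: [(strain_id, records), ...]}."""
    panel: dict[str, list] = {}
    sidx = 0
    for group, rates in groups.items():
        panel[group] = []
        for rate in rates:
            sidx += 1
            rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 100 + sidx]))
            recs = []
            for r in reference:
                arr = np.array(list(r.seq))
                n_mut = rng.binomial(len(arr), rate)
                pos = rng.choice(len(arr), size=n_mut, replace=False)
                for p in pos:
                    choices = [b for b in "ACGT" if b != arr[p]]
                    arr[p] = choices[int(rng.integers(0, 3))]
                recs.append(SequenceRecord(r.id, "".join(arr)))
            panel[group].append((f"{group}_{sidx}", recs))
    return panel
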