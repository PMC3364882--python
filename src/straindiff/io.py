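"""Readers/writers for standard genomics formats and the shared coordinate model.

All in-memory coordinates are 0-based, half-open. Conversion to each format's
native convention (VCF/GFF3 1-based inclusive, BED 0-based half-open) happens
only at the serialization boundary.
"""

from __future__ import annotations

import gzip
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Malformed input file; message names the offending line when known."""


class UnsupportedFormatError(ValueError):
    """Requested call-type/format combination has no serializer."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid interval {self.seq_id}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}, uppercase.

    Lowercase (soft-masked) stretches of the source file are preserved as
    half-open (start, end) tuples in ``softmask``.
    """

    id: str
    seq: str
    softmask: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A gene with ordered, non-overlapping CDS intervals (5'->3')."""

    gene_id: str
    interval: GenomicInterval
    cds_intervals: list[GenomicInterval]
    strand: str

    def __post_init__(self):
        ivs = sorted(self.cds_intervals, key=lambda g: g.start)
        for a, b in zip(ivs, ivs[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping CDS in gene {self.gene_id}")
        # stored genome-sorted; 5'->3' order is derived from strand
        self.cds_intervals = ivs

    @property
    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.cds_intervals)

    def cds_sequence(self, refs: dict[str, str]) -> str:
        parts = [refs[iv.seq_id][iv.start : iv.end] for iv in self.cds_intervals]
        s = "".join(parts)
        return revcomp(s) if self.strand == "-" else s


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def parse_sequences(path, format: str = "fasta") -> list[SequenceRecord]:
    """Read a FASTA file into uppercase SequenceRecords.

    Lowercase input is preserved as a soft-mask annotation. Non-IUPAC
    characters raise :class:`ParseError` naming the offending line.
    """
    if format.lower() != "fasta":
        raise UnsupportedFormatError(f"unsupported sequence format {format!r}")
    records: list[SequenceRecord] = []
    with _open(path) as fh:
        text = fh.read()
    # biopython does the structural parse; character validation is done here
    # against the raw text so errors can name a line number.
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">") or not line.strip():
            continue
        bad = set(line.strip().upper()) - VALID_BASES
        if bad:
            raise ParseError(
                f"{path}: non-IUPAC character(s) {sorted(bad)} at line {lineno}"
            )
    for rec in SeqIO.parse(_stdio.StringIO(text), "fasta"):
        raw = str(rec.seq)
        if not raw:
            raise ParseError(f"{path}: empty sequence for record {rec.id!r}")
        mask, start = [], None
        for i, c in enumerate(raw):
            if c.islower() and start is None:
                start = i
            elif not c.islower() and start is not None:
                mask.append((start, i))
                start = None
        if start is not None:
            mask.append((start, len(raw)))
        records.append(SequenceRecord(id=rec.id, seq=raw.upper(), softmask=mask))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with _open(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# BED / bedGraph


def write_bed(intervals: Iterable, path, extra_cols=None) -> None:
    """Write intervals (0-based half-open) as BED. ``extra_cols`` maps each
    interval to a list of additional columns."""
    with _open(path, "wt") as fh:
        for iv in intervals:
            row = [iv.seq_id, str(iv.start), str(iv.end)]
            if extra_cols is not None:
                row += [str(c) for c in extra_cols(iv)]
            elif iv.strand != ".":
                row += [".", "0", iv.strand]
            fh.write("\t".join(row) + "\n")


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: short BED line {lineno}")
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_bedgraph(depth: dict[str, np.ndarray], path) -> None:
    """Write per-base depth arrays as bedGraph (runs of equal value merged)."""
    with _open(path, "wt") as fh:
        for seq_id in depth:
            arr = np.asarray(depth[seq_id])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{seq_id}\t{s}\t{e}\t{arr[s]:g}\n")


def read_bedgraph(path, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    depth = {sid: np.zeros(n) for sid, n in lengths.items()}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{path}: bad bedGraph line {lineno}")
            sid, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if sid not in depth:
                raise ParseError(f"{path}: unknown sequence {sid!r} at line {lineno}")
            depth[sid][s:e] = v
    return depth


# ---------------------------------------------------------------------------
# GFF3 gene models


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                "\t".join(
                    [
                        iv.seq_id,
                        "straindiff",
                        "gene",
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )
            for i, cds in enumerate(g.cds_intervals):
                fh.write(
                    "\t".join(
                        [
                            cds.seq_id,
                            "straindiff",
                            "CDS",
                            str(cds.start + 1),
                            str(cds.end),
                            ".",
                            g.strand,
                            "0",
                            f"ID={g.gene_id}.cds{i};Parent={g.gene_id}",
                        ]
                    )
                    + "\n"
                )


def read_gff3(path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}: bad GFF3 line {lineno}")
            sid, _, ftype, start, end, _, strand, _, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            iv = GenomicInterval(sid, int(start) - 1, int(end), strand)
            if ftype == "gene":
                gid = attr.get("ID", f"gene{lineno}")
                genes[gid] = {"interval": iv, "strand": strand, "cds": []}
                order.append(gid)
            elif ftype == "CDS":
                gid = attr.get("Parent")
                if gid in genes:
                    genes[gid]["cds"].append(iv)
    return [
        GeneModel(gid, genes[gid]["interval"], genes[gid]["cds"], genes[gid]["strand"])
        for gid in order
    ]


# ---------------------------------------------------------------------------
# VCF 4.2 (variant calls; see straindiff.variants for the call type)

_VCF_HEADER = """##fileformat=VCFv4.2
##source=straindiff
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Gene effect">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">
##INFO=<ID=TRF,Number=0,Type=Flag,Description="In tandem repeat">
##INFO=<ID=BLOCK,Number=1,Type=String,Description="Source alignment block">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: Sequence, refs: dict[str, str], path, annotations=None) -> None:
    """Write variant calls as VCF 4.2 (1-based; indels anchored on the
    preceding base per convention)."""
    ann_by_id = {}
    if annotations:
        ann_by_id = {a.variant_id: a for a in annotations}
    with _open(path, "wt") as fh:
        fh.write(_VCF_HEADER)
        for i, c in enumerate(calls):
            info = []
            a = ann_by_id.get(c.variant_id)
            if a is not None:
                info.append(f"EFFECT={a.effect}")
                if a.gene_id:
                    info.append(f"GENE={a.gene_id}")
            if c.in_tandem_repeat:
                info.append("TRF")
            if c.block_id is not None:
                info.append(f"BLOCK={c.block_id}")
            seq = refs[c.seq_id]
            if c.kind == "snv":
                pos, ref, alt = c.pos + 1, c.ref, c.alt
            elif c.kind == "deletion":
                anchor = seq[c.pos - 1] if c.pos > 0 else "N"
                pos, ref, alt = c.pos, anchor + c.ref, anchor
            else:  # insertion
                anchor = seq[c.pos - 1] if c.pos > 0 else "N"
                pos, ref, alt = c.pos, anchor, anchor + c.alt
            fh.write(
                f"{c.seq_id}\t{pos}\t{c.variant_id or 'v%d' % i}\t{ref}\t{alt}"
                f"\t.\tPASS\t{';'.join(info) or '.'}\n"
            )


def read_vcf(path):
    """Read a straindiff-dialect VCF back into VariantCall objects."""
    from .variants import VariantCall

    calls = []
    with _open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, pos, vid, ref, alt, _, _, info = line.rstrip("\n").split("\t")[:8]
            pos = int(pos)
            flags = info.split(";")
            trf = "TRF" in flags
            block = next(
                (f.split("=", 1)[1] for f in flags if f.startswith("BLOCK=")), None
            )
            if len(ref) == 1 and len(alt) == 1:
                calls.append(
                    VariantCall(
                        kind="snv", seq_id=chrom, pos=pos - 1, ref=ref, alt=alt,
                        block_id=block, in_tandem_repeat=trf, variant_id=vid,
                    )
                )
            elif len(ref) > len(alt):
                calls.append(
                    VariantCall(
                        kind="deletion", seq_id=chrom, pos=pos, ref=ref[1:], alt="",
                        block_id=block, in_tandem_repeat=trf, variant_id=vid,
                    )
                )
            else:
                calls.append(
                    VariantCall(
                        kind="insertion", seq_id=chrom, pos=pos, ref="", alt=alt[1:],
                        block_id=block, in_tandem_repeat=trf, variant_id=vid,
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# Newick


def write_newick(newick: str, path) -> None:
    with _open(path, "wt") as fh:
        fh.write(newick.rstrip() + ("\n" if not newick.rstrip().endswith(";") else "\n"))


def read_newick(path):
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# Dispatching serializer


def serialize_calls(calls, format: str, path, **kwargs) -> None:
    """Serialize a call collection to ``path`` in the requested format.

    Formats: VCF (variant calls), BED (intervals), GFF3 (gene models),
    TSV (pandas DataFrame), Newick (tree string).
    """
    fmt = format.lower()
    if fmt == "vcf":
        return write_vcf(calls, kwargs.pop("refs"), path, **kwargs)
    if fmt == "bed":
        return write_bed(calls, path, **kwargs)
    if fmt == "gff3":
        return write_gff3(calls, path)
    if fmt == "tsv":
        calls.to_csv(path, sep="\t", index=False)
        return None
    if fmt == "newick":
        return write_newick(calls, path)
    raise UnsupportedFormatError(f"no serializer for format {format!r}")
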