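"""Readers and writers: GTF, FASTA, SAM/BAM, CIRI2-style junction tables, BED.

GTF and CIRI2-style tables are 1-based inclusive on disk; everything is
converted to the internal 0-based half-open convention here and only here.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path

import pysam
from pyfaidx import Fasta

from .model import AlignedRead, CircCall, Genome, Interval, Transcript, TranscriptCatalog

log = logging.getLogger(__name__)


class GtfParseError(ValueError):
    pass


class Ciri2FormatError(ValueError):
    pass


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def parse_gtf(path: str | Path) -> TranscriptCatalog:
    """Build a transcript catalog from the exon lines of a GTF file.

    Only ``exon`` features are used; transcripts are reconstructed by
    grouping exons on ``transcript_id``. Single-exon transcripts are
    retained (they simply contribute no introns).
    """
    exons: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str]] = {}  # tid -> (gene_id, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            contig, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            attr = _parse_attributes(attrs)
            tid = attr.get("transcript_id")
            if not tid:
                raise GtfParseError(f"line {lineno}: exon without transcript_id")
            gene = attr.get("gene_id", tid)
            try:
                iv = Interval(contig, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: {exc}") from exc
            exons.setdefault(tid, []).append(iv)
            meta.setdefault(tid, (gene, strand))
    catalog = TranscriptCatalog()
    for tid, ivs in exons.items():
        gene, strand = meta[tid]
        catalog.add(Transcript(tid, gene, strand, ivs))
    return catalog


def write_gtf(catalog: TranscriptCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in catalog:
            for i, exon in enumerate(t.exons, start=1):
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'exon_number "{i}";'
                )
                fh.write(
                    f"{exon.contig}\teicirna\texon\t{exon.start + 1}\t{exon.end}"
                    f"\t.\t{t.strand}\t.\t{attrs}\n"
                )


def load_genome(path: str | Path) -> Genome:
    """Load a FASTA into memory (toy genomes here are kilobase-scale)."""
    fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return Genome({name: str(fasta[name][:]) for name in fasta.keys()})


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.contig_names():
            fh.write(f">{name}\n")
            seq = genome.sequence(name)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


CIRI2_COLUMNS = [
    "circRNA_ID", "chr", "circRNA_start", "circRNA_end", "#junction_reads",
    "SM_MS_SMS", "#non_junction_reads", "junction_reads_ratio", "circRNA_type",
    "gene_id", "strand", "junction_reads_ID",
]
_REQUIRED = {
    "circRNA_ID", "chr", "circRNA_start", "circRNA_end",
    "#junction_reads", "circRNA_type", "strand", "junction_reads_ID",
}


def parse_ciri2(path: str | Path) -> list[CircCall]:
    """Parse a CIRI2-format circRNA table into calls.

    Coordinates on disk are 1-based inclusive; rows are kept in input
    order, and no type filtering happens here (selecting ``exon``-type
    calls is a pipeline step).
    """
    calls: list[CircCall] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise Ciri2FormatError("empty file (no header)")
        header = header_line.rstrip("\n").split("\t")
        missing = _REQUIRED - set(header)
        if missing:
            raise Ciri2FormatError(f"missing required columns: {sorted(missing)}")
        col = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(header):
                fields += [""] * (len(header) - len(fields))
            try:
                count = int(fields[col["#junction_reads"]])
            except ValueError as exc:
                raise Ciri2FormatError(
                    f"line {lineno}: non-integer junction read count "
                    f"{fields[col['#junction_reads']]!r}"
                ) from exc
            try:
                start = int(fields[col["circRNA_start"]]) - 1
                end = int(fields[col["circRNA_end"]])
            except ValueError as exc:
                raise Ciri2FormatError(f"line {lineno}: bad coordinates") from exc
            ids_field = fields[col["junction_reads_ID"]].strip().rstrip(",")
            read_ids = [r for r in ids_field.split(",") if r] if ids_field else []
            calls.append(
                CircCall(
                    circ_id=fields[col["circRNA_ID"]],
                    interval=Interval(
                        fields[col["chr"]], start, end,
                        fields[col["strand"]] or ".",
                    ),
                    bsj_count=count,
                    circ_type=fields[col["circRNA_type"]],
                    read_ids=read_ids,
                )
            )
    return calls


def write_ciri2(calls: list[CircCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CIRI2_COLUMNS) + "\n")
        for c in calls:
            iv = c.interval
            row = {
                "circRNA_ID": c.circ_id,
                "chr": iv.contig,
                "circRNA_start": str(iv.start + 1),
                "circRNA_end": str(iv.end),
                "#junction_reads": str(c.bsj_count),
                "SM_MS_SMS": "0_0_0",
                "#non_junction_reads": "0",
                "junction_reads_ratio": "1.0",
                "circRNA_type": c.circ_type,
                "gene_id": "n/a",
                "strand": iv.strand,
                "junction_reads_ID": ",".join(c.read_ids),
            }
            fh.write("\t".join(row[k] for k in CIRI2_COLUMNS) + "\n")


def write_bed6(calls: list[CircCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            iv = c.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{c.circ_id}"
                f"\t{c.bsj_count}\t{iv.strand}\n"
            )


_CIGAR_OPS = "MIDNSHP=X"


def _from_pysam(rec: pysam.AlignedSegment) -> AlignedRead:
    cigar = [(_CIGAR_OPS[op], n) for op, n in rec.cigartuples or []]
    mate = 1 if rec.is_read1 else (2 if rec.is_read2 else 0)
    return AlignedRead(
        read_id=rec.query_name,
        mate=mate,
        contig=rec.reference_name,
        start=rec.reference_start,
        cigar=cigar,
        mapping_quality=rec.mapping_quality,
        is_reverse=rec.is_reverse,
    )


def read_alignments(
    path: str | Path,
    region: Interval | None = None,
    include_secondary: bool = False,
    min_mapq: int = 0,
):
    """Iterate mapped primary alignments from a SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped unless
    ``include_secondary`` is set. A region query requires a
    coordinate-sorted, indexed file.
    """
    path = str(path)
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as af:
        if region is not None:
            if not af.has_index():
                raise ValueError(
                    f"{path}: region queries need a coordinate-sorted, indexed "
                    "file (samtools sort && samtools index)"
                )
            it = af.fetch(region.contig, region.start, region.end)
        else:
            it = af.fetch(until_eof=True)
        for rec in it:
            if rec.is_unmapped:
                continue
            if not include_secondary and (rec.is_secondary or rec.is_supplementary):
                continue
            if rec.mapping_quality < min_mapq:
                continue
            yield _from_pysam(rec)


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> dict[str, tuple[str, str]]:
    """Load a paired FASTQ into {read id: (mate1 seq, mate2 seq)}."""
    pairs: dict[str, list[str | None]] = {}
    for idx, path in ((0, r1_path), (1, r2_path)):
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                name = entry.name.split("/")[0]
                pairs.setdefault(name, [None, None])[idx] = entry.sequence
    out = {}
    for name, (s1, s2) in pairs.items():
        if s1 is None or s2 is None:
            log.warning("read %s missing a mate; skipped", name)
            continue
        out[name] = (s1, s2)
    return out
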