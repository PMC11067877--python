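"""Shared genomic data model.

All coordinates are 0-based half-open on the plus strand, BED-style.
File formats that use 1-based inclusive coordinates (GTF, CIRI2-like
junction tables) are converted at the I/O boundary and nowhere else.
"""
from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STRANDS = ("+", "-", ".")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start},{self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


class Genome:
    """In-memory genome: uppercase DNA keyed by contig name.

    Thin and dict-backed so simulators and tests can build genomes
    without touching the filesystem; FASTA loading lives in io.
    """

    def __init__(self, contigs: dict[str, str]):
        if not contigs:
            raise ValueError("genome has no contigs")
        self._contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} has empty sequence")
            self._contigs[name] = seq.upper()

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def contig_names(self) -> list[str]:
        return list(self._contigs)

    def contig_length(self, name: str) -> int:
        return len(self._contigs[name])

    def sequence(self, name: str) -> str:
        return self._contigs[name]

    def fetch(self, interval: Interval) -> str:
        """Sequence of an interval; reverse-complemented on the minus strand.

        Strand "." is treated as "+" (with a debug-level note): the
        retention metrics downstream are strand-symmetric.
        """
        if interval.contig not in self._contigs:
            raise KeyError(f"unknown contig {interval.contig!r}")
        seq = self._contigs[interval.contig]
        if interval.end > len(seq):
            raise IndexError(
                f"interval [{interval.start},{interval.end}) beyond contig "
                f"{interval.contig!r} length {len(seq)}"
            )
        sub = seq[interval.start : interval.end]
        if interval.strand == "-":
            return reverse_complement(sub)
        if interval.strand == ".":
            log.debug("strand '.' treated as '+' for %s", interval)
        return sub


@dataclass(frozen=True)
class IntronInterval:
    """An intron of a transcript with its 5'->3' ordinal (1-based)."""

    interval: Interval
    transcript_id: str
    ordinal: int

    @property
    def key(self) -> tuple[str, int, int]:
        """Coordinate identity, used for dedup across host transcripts."""
        return (self.interval.contig, self.interval.start, self.interval.end)

    @property
    def name(self) -> str:
        iv = self.interval
        return f"{iv.contig}:{iv.start}-{iv.end}"


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    strand: str
    exons: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping exons in {self.transcript_id}: {a} / {b}"
                )

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def introns(self) -> list[IntronInterval]:
        """Gaps between consecutive exons, ordinal numbered 5'->3'.

        On the minus strand the genomically last gap is ordinal 1.
        Zero-length gaps (abutting exons) are skipped with a warning.
        """
        gaps = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start == a.end:
                log.warning(
                    "abutting exons in %s at %s:%d; intron omitted",
                    self.transcript_id, a.contig, a.end,
                )
                continue
            gaps.append(Interval(a.contig, a.end, b.start, self.strand))
        n = len(gaps)
        out = []
        for i, gap in enumerate(gaps):
            ordinal = i + 1 if self.strand != "-" else n - i
            out.append(IntronInterval(gap, self.transcript_id, ordinal))
        return out


class TranscriptCatalog:
    """Transcripts indexed by id with a simple per-contig overlap index."""

    def __init__(self, transcripts: list[Transcript] | None = None):
        self._by_id: dict[str, Transcript] = {}
        self._index: dict[str, list[tuple[int, int, str]]] = {}
        self._starts: dict[str, list[int]] = {}
        for t in transcripts or []:
            self.add(t)

    def add(self, transcript: Transcript) -> None:
        if transcript.transcript_id in self._by_id:
            raise ValueError(f"duplicate transcript id {transcript.transcript_id}")
        self._by_id[transcript.transcript_id] = transcript
        self._index.pop(transcript.contig, None)  # invalidate

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def __iter__(self):
        return iter(self._by_id.values())

    def get(self, transcript_id: str) -> Transcript:
        return self._by_id[transcript_id]

    def transcript_ids(self) -> list[str]:
        return list(self._by_id)

    def _build_index(self, contig: str) -> None:
        entries = sorted(
            (t.start, t.end, t.transcript_id)
            for t in self._by_id.values()
            if t.contig == contig
        )
        self._index[contig] = entries
        self._starts[contig] = [e[0] for e in entries]

    def overlapping(self, interval: Interval) -> list[Transcript]:
        """Transcripts whose span overlaps the interval."""
        if interval.contig not in self._index:
            self._build_index(interval.contig)
        entries = self._index[interval.contig]
        hi = bisect_left(self._starts[interval.contig], interval.end)
        hits = [
            self._by_id[tid]
            for start, end, tid in entries[:hi]
            if end > interval.start
        ]
        return hits

    def validate_against(self, genome: Genome) -> None:
        for t in self._by_id.values():
            if t.contig not in genome:
                raise ValueError(
                    f"transcript {t.transcript_id} on unknown contig {t.contig!r}"
                )
            if t.end > genome.contig_length(t.contig):
                raise ValueError(
                    f"transcript {t.transcript_id} extends beyond contig {t.contig!r}"
                )


CIRC_TYPES = ("exon", "intron", "intergenic")


@dataclass
class CircCall:
    """One back-splice junction call.

    The interval spans the circle's genomic footprint: start is the
    acceptor (5' circularized exon start), end the donor (3' exon end).
    """

    circ_id: str
    interval: Interval
    bsj_count: int
    circ_type: str
    read_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.bsj_count < 0:
            raise ValueError("negative BSJ count")
        if self.circ_type not in CIRC_TYPES:
            raise ValueError(f"bad circRNA type {self.circ_type!r}")
        if self.read_ids and self.bsj_count < len(self.read_ids):
            raise ValueError(
                f"{self.circ_id}: BSJ count {self.bsj_count} < "
                f"{len(self.read_ids)} listed read ids"
            )


_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")
_BLOCK_OPS = frozenset("MD=X")  # D stays inside a block; N splits


@dataclass
class AlignedRead:
    """A linear alignment record reduced to what the metrics need."""

    read_id: str
    mate: int  # 1 or 2; 0 if unpaired
    contig: str
    start: int  # leftmost reference position, 0-based
    cigar: list[tuple[str, int]]
    mapping_quality: int = 60
    is_reverse: bool = False

    def __post_init__(self) -> None:
        bad = [op for op, _ in self.cigar if op not in "MIDNSH=X"]
        if bad:
            raise ValueError(f"unsupported CIGAR ops {bad}")

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _QUERY_OPS)

    @property
    def end(self) -> int:
        return self.start + sum(n for op, n in self.cigar if op in _REF_OPS)

    def blocks(self) -> list[tuple[int, int]]:
        """Aligned reference blocks, split at N gaps only.

        D consumes reference within a block (a deletion does not break
        junction evidence); I/S/H consume no reference.
        """
        out: list[tuple[int, int]] = []
        pos = self.start
        block_start = None
        for op, n in self.cigar:
            if op in _BLOCK_OPS:
                if block_start is None:
                    block_start = pos
                pos += n
            elif op == "N":
                if block_start is not None:
                    out.append((block_start, pos))
                    block_start = None
                pos += n
            # I, S, H: no reference advance
        if block_start is not None:
            out.append((block_start, pos))
        return out

    def gaps(self) -> list[tuple[int, int]]:
        """Reference intervals skipped by N operations (introns spliced out)."""
        blocks = self.blocks()
        return [(a[1], b[0]) for a, b in zip(blocks, blocks[1:])]
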