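import re

import numpy as np
import pytest

from eicirna.model import AlignedRead, Genome, Interval, Transcript, TranscriptCatalog


def parse_cigar_string(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar)]


def read_from(cigar: str, pos: int, contig: str = "chrT", rid: str = "r",
              mate: int = 1, mapq: int = 60) -> AlignedRead:
    return AlignedRead(rid, mate, contig, pos, parse_cigar_string(cigar), mapq)


def alignments_from_sim(sim_result) -> list[AlignedRead]:
    """Convert simulator SAM records to the in-memory alignment model."""
    return [
        AlignedRead(
            r.qname,
            1 if r.flag & 0x40 else 2,
            r.contig,
            r.pos,
            parse_cigar_string(r.cigar),
            r.mapq,
            bool(r.flag & 0x10),
        )
        for r in sim_result.sam_records
    ]


@pytest.fixture
def three_exon_transcript() -> Transcript:
    exons = [
        Interval("chrT", 0, 100, "+"),
        Interval("chrT", 200, 300, "+"),
        Interval("chrT", 400, 500, "+"),
    ]
    return Transcript("tx1", "g1", "+", exons)


@pytest.fixture
def random_genome() -> Genome:
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    return Genome({"chrT": seq})


def random_catalog(rng: np.random.Generator, n_transcripts: int,
                   contig: str = "chrT") -> TranscriptCatalog:
    """Random multi-exon transcripts for brute-force comparisons."""
    catalog = TranscriptCatalog()
    for i in range(n_transcripts):
        n_exons = int(rng.integers(1, 6))
        pos = int(rng.integers(0, 500))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(20, 120))
            exons.append(Interval(contig, pos, pos + length, "+"))
            pos += length + int(rng.integers(1, 200))
        catalog.add(Transcript(f"tx{i}", f"g{i}", "+", exons))
    return catalog
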