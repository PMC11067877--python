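"""Host-transcript assignment for circRNA calls.

A call is scored against each overlapping transcript by how many of its
two back-splice boundaries coincide exactly with annotated exon
boundaries (0, 1 or 2); all transcripts achieving the maximal score are
kept as hosts, and the candidate internal introns are the union of the
hosts' introns falling strictly inside the circle span.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .model import CircCall, IntronInterval, Transcript, TranscriptCatalog


@dataclass
class HostAssignment:
    circ_id: str
    score: int
    host_transcript_ids: list[str]
    internal_introns: list[IntronInterval] = field(default_factory=list)

    @property
    def unannotated(self) -> bool:
        return not self.host_transcript_ids


def score_transcript(circ: CircCall, transcript: Transcript) -> int:
    """Boundary-match score in {0, 1, 2}.

    2 if the circle start equals some exon start AND the circle end
    equals some exon end of the transcript; 1 if exactly one boundary
    matches; 0 otherwise. Matching is exact — back-splice junctions are
    splice-site anchored, so no tolerance is applied.
    """
    if circ.interval.contig != transcript.contig:
        raise ValueError(
            f"contig mismatch: circ {circ.circ_id} on {circ.interval.contig}, "
            f"transcript {transcript.transcript_id} on {transcript.contig}"
        )
    start_match = any(e.start == circ.interval.start for e in transcript.exons)
    end_match = any(e.end == circ.interval.end for e in transcript.exons)
    return int(start_match) + int(end_match)


def _strand_compatible(circ: CircCall, transcript: Transcript) -> bool:
    return circ.interval.strand == "." or circ.interval.strand == transcript.strand


def assign_hosts(
    circ: CircCall,
    catalog: TranscriptCatalog,
    union_introns: bool = True,
) -> HostAssignment:
    """Pick host transcripts at the maximal boundary score.

    Ties keep all transcripts; their internal introns are unioned
    (deduplicated by coordinates) by default, or intersected when
    ``union_introns`` is False.
    """
    candidates = [
        t for t in catalog.overlapping(circ.interval) if _strand_compatible(circ, t)
    ]
    if not candidates:
        return HostAssignment(circ.circ_id, 0, [], [])
    scored = [(score_transcript(circ, t), t) for t in candidates]
    best = max(s for s, _ in scored)
    hosts = [t for s, t in scored if s == best]

    per_host: list[dict[tuple, IntronInterval]] = []
    for t in hosts:
        inside = {
            i.key: i
            for i in t.introns()
            if i.interval.start >= circ.interval.start
            and i.interval.end <= circ.interval.end
        }
        per_host.append(inside)
    if union_introns:
        merged: dict[tuple, IntronInterval] = {}
        for d in per_host:
            for k, v in d.items():
                merged.setdefault(k, v)
    else:
        keys = set(per_host[0]) if per_host else set()
        for d in per_host[1:]:
            keys &= set(d)
        merged = {k: per_host[0][k] for k in keys}
    introns = sorted(merged.values(), key=lambda i: (i.interval.start, i.interval.end))
    return HostAssignment(
        circ.circ_id, best, sorted(t.transcript_id for t in hosts), introns
    )


def write_assignments(assignments: list[HostAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("circ_id\tscore\thost_transcripts\tn_internal_introns\n")
        for a in assignments:
            fh.write(
                f"{a.circ_id}\t{a.score}\t{','.join(a.host_transcript_ids)}"
                f"\t{len(a.internal_introns)}\n"
            )
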