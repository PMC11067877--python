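"""End-to-end EIciRNA detection: the three-step pipeline as a library call.

Step 1 (input): circRNA calls from an external caller (CIRI2-format
table), restricted to exon-type calls.  Step 2: host-transcript
assignment, circular pseudo-reference construction, placement and
classification of BSJ read pairs for intronic evidence.  Step 3:
per-intron retention metrics on the genome alignments and validation;
validated circles become EIciRNA records with BRPM quantification.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from . import evidence as ev
from .hosts import HostAssignment, assign_hosts
from .model import AlignedRead, CircCall, Genome, TranscriptCatalog
from .quantify import brpm
from .retention import (
    EIciRNARecord,
    RetentionMetrics,
    RetentionThresholds,
    call_eicirnas,
    compute_metrics,
)


@dataclass
class DetectConfig:
    read_length: int = 150
    overhang: int = 5
    thresholds: RetentionThresholds = field(default_factory=RetentionThresholds)
    placement: ev.PlacementConfig = field(default_factory=ev.PlacementConfig)
    min_support: int = 1
    min_mapq: int = 1
    total_mapped_reads: int | None = None  # default: count of input alignments


@dataclass
class DetectResult:
    records: list[EIciRNARecord]
    assignments: dict[str, HostAssignment]
    evidence: list[ev.PairEvidence]
    candidates: list[ev.Candidate]
    metrics: dict[tuple, RetentionMetrics]
    report: dict


def detect(
    genome: Genome,
    catalog: TranscriptCatalog,
    calls: list[CircCall],
    alignments: list[AlignedRead],
    read_pairs: dict[str, tuple[str, str]],
    config: DetectConfig | None = None,
) -> DetectResult:
    """Run the full detection pipeline on in-memory inputs.

    ``alignments`` are genome alignments of the whole library (used for
    retention metrics and the BRPM denominator); ``read_pairs`` maps
    read ids to mate sequences for BSJ pair placement.
    """
    cfg = config or DetectConfig()
    bad_contigs = sorted(
        {a.contig for a in alignments} - set(genome.contig_names())
    )
    if bad_contigs:
        raise ValueError(
            f"alignment contigs absent from genome: {', '.join(bad_contigs)}"
        )
    exon_calls = [c for c in calls if c.circ_type == "exon"]

    assignments: dict[str, HostAssignment] = {}
    pair_evidence: list[ev.PairEvidence] = []
    for call in exon_calls:
        assignment = assign_hosts(call, catalog)
        assignments[call.circ_id] = assignment
        if assignment.unannotated or not assignment.internal_introns:
            continue
        pseudo = ev.build_pseudo_reference(call, genome, cfg.read_length)
        index = ev.kmer_index(pseudo.sequence, cfg.placement.seed_k)
        for rid, seq1, seq2 in ev.extract_bsj_read_pairs(call, read_pairs):
            placed = ev.place_pair(rid, seq1, seq2, pseudo, cfg.placement, index)
            if placed is None:
                pair_evidence.append(
                    ev.PairEvidence(call.circ_id, rid, "unplaced")
                )
                continue
            pair_evidence.append(
                ev.classify_pair(placed, pseudo, assignment.internal_introns,
                                 cfg.overhang)
            )

    candidates = ev.candidate_eicirnas(exon_calls, pair_evidence, cfg.min_support)

    usable = [a for a in alignments if a.mapping_quality >= cfg.min_mapq]
    metrics: dict[tuple, RetentionMetrics] = {}
    for cand in candidates:
        if cand.intron.key in metrics:
            continue
        iv = cand.intron.interval
        local = [
            a for a in usable
            if a.contig == iv.contig and a.start < iv.end + 1 and a.end > iv.start - 1
        ]
        metrics[cand.intron.key] = compute_metrics(local, cand.intron, cfg.overhang)

    records = call_eicirnas(candidates, metrics, exon_calls, assignments,
                            cfg.thresholds)
    total = cfg.total_mapped_reads or len(alignments)
    for r in records:
        r.brpm = brpm(r.bsj_count, total) if total else None

    report = {
        "n_calls": len(calls),
        "n_exon_type": len(exon_calls),
        "n_assigned": sum(
            1 for a in assignments.values()
            if not a.unannotated and a.internal_introns
        ),
        "n_pairs_classified": len(pair_evidence),
        "n_candidates": len(candidates),
        "n_eicirnas": len(records),
        "total_mapped_reads": total,
    }
    return DetectResult(records, assignments, pair_evidence, candidates,
                        metrics, report)
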