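"""Per-intron retention metrics and EIciRNA validation.

For each candidate intron, genome alignments yield five metrics:

* ``EE`` — spliced reads whose N gap matches the intron exactly,
* ``EI`` / ``IE`` — unspliced reads whose aligned block crosses the
  exon-intron (resp. intron-exon) boundary,
* ``I``  — reads confined to the intron that touch its middle window
  (the centered 200 nt, or the whole intron when shorter),
* ``IC`` — fraction of intron positions covered by at least one read.

All junction evidence requires a minimum overhang (default 5 nt) on both
sides of the junction. An intron validates as retained when
EE >= 1, EI >= 1, IE >= 1, I >= 1 and IC >= 0.9. PIR (percent intron
retention) is the junction-based ratio mean(EI, IE) / (mean(EI, IE) + EE).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .evidence import Candidate
from .hosts import HostAssignment
from .model import AlignedRead, CircCall, IntronInterval

MIDDLE_WINDOW = 200


@dataclass
class RetentionMetrics:
    intron: IntronInterval
    ee: int = 0
    ei: int = 0
    ie: int = 0
    i: int = 0
    ic: float = 0.0

    @property
    def pir(self) -> float:
        return compute_pir(self.ee, self.ei, self.ie)


@dataclass
class RetentionThresholds:
    min_ee: int = 1
    min_ei: int = 1
    min_ie: int = 1
    min_i: int = 1
    min_ic: float = 0.9
    overhang: int = 5


def count_junction_reads(
    alignments: Iterable[AlignedRead],
    intron: IntronInterval,
    overhang: int = 5,
) -> tuple[int, int, int]:
    """(EE, EI, IE) junction-read counts for one intron.

    A read whose N gap equals the intron exactly (with >= overhang
    aligned bases flanking both gap ends) counts once toward EE and is
    excluded from EI/IE for this intron. An unspliced block crossing a
    boundary with >= overhang bases on each side counts toward EI (start
    boundary) or IE (end boundary); a read spanning the whole intron may
    contribute to both boundaries but only once to each.
    """
    iv = intron.interval
    ee = ei = ie = 0
    for read in alignments:
        blocks = read.blocks()
        is_ee = False
        for idx in range(len(blocks) - 1):
            gap = (blocks[idx][1], blocks[idx + 1][0])
            if gap == (iv.start, iv.end):
                left = blocks[idx][1] - blocks[idx][0]
                right = blocks[idx + 1][1] - blocks[idx + 1][0]
                if left >= overhang and right >= overhang:
                    is_ee = True
                break
        if is_ee:
            ee += 1
            continue
        hit_ei = any(
            b0 <= iv.start - overhang and b1 >= iv.start + overhang
            for b0, b1 in blocks
        )
        hit_ie = any(
            b0 <= iv.end - overhang and b1 >= iv.end + overhang
            for b0, b1 in blocks
        )
        ei += hit_ei
        ie += hit_ie
    return ee, ei, ie


def middle_window(intron: IntronInterval, size: int = MIDDLE_WINDOW) -> tuple[int, int]:
    """Centered window of ``size`` nt, or the whole intron when shorter."""
    iv = intron.interval
    if len(iv) <= size:
        return iv.start, iv.end
    offset = (len(iv) - size) // 2
    return iv.start + offset, iv.start + offset + size


def count_middle_window(
    alignments: Iterable[AlignedRead], intron: IntronInterval
) -> int:
    """Reads with aligned bases in the intron's middle window.

    A read counts only if every aligned block of it that overlaps the
    intron lies entirely inside the intron — boundary-crossing reads are
    junction evidence, not middle-of-intron evidence.
    """
    iv = intron.interval
    w0, w1 = middle_window(intron)
    n = 0
    for read in alignments:
        blocks = read.blocks()
        touching = [b for b in blocks if b[0] < iv.end and b[1] > iv.start]
        if not touching:
            continue
        if any(b0 < iv.start or b1 > iv.end for b0, b1 in touching):
            continue
        if any(b0 < w1 and b1 > w0 for b0, b1 in touching):
            n += 1
    return n


def intron_coverage(
    alignments: Iterable[AlignedRead], intron: IntronInterval
) -> float:
    """Fraction of intron positions covered by >= 1 aligned block."""
    iv = intron.interval
    covered = np.zeros(len(iv), dtype=bool)
    for read in alignments:
        for b0, b1 in read.blocks():
            lo = max(b0, iv.start) - iv.start
            hi = min(b1, iv.end) - iv.start
            if hi > lo:
                covered[lo:hi] = True
    return float(covered.mean())


def compute_pir(ee: int, ei: int, ie: int) -> float:
    """PIR = mean(EI, IE) / (mean(EI, IE) + EE); 0 when all are zero."""
    m = (ei + ie) / 2.0
    if m + ee == 0:
        return 0.0
    return m / (m + ee)


def compute_metrics(
    alignments: list[AlignedRead],
    intron: IntronInterval,
    overhang: int = 5,
) -> RetentionMetrics:
    ee, ei, ie = count_junction_reads(alignments, intron, overhang)
    return RetentionMetrics(
        intron,
        ee=ee,
        ei=ei,
        ie=ie,
        i=count_middle_window(alignments, intron),
        ic=intron_coverage(alignments, intron),
    )


def validate_retention(
    metrics: RetentionMetrics,
    thresholds: RetentionThresholds | None = None,
) -> bool:
    t = thresholds or RetentionThresholds()
    return (
        metrics.ee >= t.min_ee
        and metrics.ei >= t.min_ei
        and metrics.ie >= t.min_ie
        and metrics.i >= t.min_i
        and metrics.ic >= t.min_ic
    )


@dataclass
class EIciRNARecord:
    circ_id: str
    interval: object  # Interval of the BSJ span
    host_transcript_ids: list[str]
    introns: list[IntronInterval]
    bsj_count: int
    metrics: dict[tuple, RetentionMetrics] = field(default_factory=dict)
    brpm: float | None = None


def call_eicirnas(
    candidates: list[Candidate],
    metrics_by_intron: dict[tuple, RetentionMetrics],
    calls: list[CircCall],
    assignments: dict[str, HostAssignment] | None = None,
    thresholds: RetentionThresholds | None = None,
) -> list[EIciRNARecord]:
    """Validate candidate introns and emit one record per passing circle.

    The record's BSJ count is the number of distinct BSJ pairs that
    provided the qualifying intron evidence (the step-2 count), not the
    caller's raw junction-read count.
    """
    by_circ: dict[str, list[Candidate]] = {}
    for c in candidates:
        by_circ.setdefault(c.circ_id, []).append(c)
    calls_by_id = {c.circ_id: c for c in calls}
    records: list[EIciRNARecord] = []
    for circ_id, cands in by_circ.items():
        validated = [
            c for c in cands
            if c.intron.key in metrics_by_intron
            and validate_retention(metrics_by_intron[c.intron.key], thresholds)
        ]
        if not validated:
            continue
        read_ids: set[str] = set()
        for c in validated:
            read_ids.update(c.read_ids)
        call = calls_by_id[circ_id]
        hosts = (
            assignments[circ_id].host_transcript_ids
            if assignments and circ_id in assignments
            else []
        )
        records.append(
            EIciRNARecord(
                circ_id=circ_id,
                interval=call.interval,
                host_transcript_ids=hosts,
                introns=sorted((c.intron for c in validated),
                               key=lambda i: i.key),
                bsj_count=len(read_ids),
                metrics={
                    c.intron.key: metrics_by_intron[c.intron.key] for c in validated
                },
            )
        )
    records.sort(key=lambda r: r.circ_id)
    return records


CIR_MIN_PIR = 0.1
NCI_MAX_PIR = 0.02
LIR_MIN_IRRATIO = 0.1


@dataclass
class IntronClassLabel:
    intron_key: tuple
    labels: list[str]
    circ_pir: float | None = None
    linear_irratio: float | None = None


def label_intron_classes(
    circ_metrics: dict[tuple, RetentionMetrics],
    ecirc_internal_keys: set[tuple],
    linear_metrics: dict[tuple, RetentionMetrics],
    thresholds: RetentionThresholds | None = None,
) -> list[IntronClassLabel]:
    """CIR / NCI / LIR class labels for introns.

    CIR: validated as retained in the circRNA context with PIR >= 0.1
    (RNase R-treated library). NCI: internal to an exonic circRNA and
    spliced out of it (circ-context PIR <= 0.02). LIR: retained in the
    linear transcript, IRratio >= 0.1 (poly(A)-plus library). An intron
    meeting several definitions carries all its labels.
    """
    keys = set(circ_metrics) | set(ecirc_internal_keys) | set(linear_metrics)
    out = []
    for key in sorted(keys):
        labels = []
        cm = circ_metrics.get(key)
        lm = linear_metrics.get(key)
        if cm is not None and validate_retention(cm, thresholds) and cm.pir >= CIR_MIN_PIR:
            labels.append("CIR")
        if key in ecirc_internal_keys and cm is not None and cm.pir <= NCI_MAX_PIR:
            labels.append("NCI")
        if lm is not None and lm.pir >= LIR_MIN_IRRATIO:
            labels.append("LIR")
        if not labels:
            labels = ["unclassified"]
        out.append(
            IntronClassLabel(
                key,
                labels,
                circ_pir=cm.pir if cm is not None else None,
                linear_irratio=lm.pir if lm is not None else None,
            )
        )
    return out


def write_records(records: list[EIciRNARecord], path: str | Path) -> None:
    cols = [
        "chrom", "start", "end", "circ_id", "strand", "host_transcripts",
        "intron_start", "intron_end", "EE", "EI", "IE", "I", "IC", "PIR",
        "bsj_count", "brpm",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            iv = r.interval
            for intron in r.introns:
                m = r.metrics[intron.key]
                fh.write("\t".join(str(x) for x in [
                    iv.contig, iv.start, iv.end, r.circ_id, iv.strand,
                    ",".join(r.host_transcript_ids),
                    intron.interval.start, intron.interval.end,
                    m.ee, m.ei, m.ie, m.i, f"{m.ic:.4f}", f"{m.pir:.4f}",
                    r.bsj_count,
                    f"{r.brpm:.4f}" if r.brpm is not None else "NA",
                ]) + "\n")


def write_bed12(records: list[EIciRNARecord], path: str | Path) -> None:
    """BED12 export: one row per record, retained introns as thick blocks."""
    with open(path, "w") as fh:
        for r in records:
            iv = r.interval
            blocks = sorted((i.interval.start, i.interval.end) for i in r.introns)
            starts = ",".join(str(b0 - iv.start) for b0, _ in blocks)
            sizes = ",".join(str(b1 - b0) for b0, b1 in blocks)
            fh.write("\t".join(str(x) for x in [
                iv.contig, iv.start, iv.end, r.circ_id, r.bsj_count, iv.strand,
                iv.start, iv.end, "0,0,0", len(blocks), sizes, starts,
            ]) + "\n")
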