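"""Back-splice-junction read evidence against circular pseudo-references.

A circle spanning genomic [start, end) is linearized as that span plus a
"rotation pad" — its first (read length - 1) bases appended again — so
any single read from the circle, wherever the back-splice junction (BSJ)
falls inside it, aligns contiguously. BSJ-supporting read pairs are
placed on the pseudo-reference with a light exact-k-mer / ungapped
extension scheme (or consumed from an external SAM), projected back to
genomic coordinates, and classified by whether a mate carries intronic
sequence: fully intronic, exon-intron boundary crossing (with a minimum
overhang on both sides), or exonic only.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .model import CircCall, Genome, Interval, IntronInterval, reverse_complement

log = logging.getLogger(__name__)

MIN_CIRC_LENGTH = 20


@dataclass
class PseudoRef:
    circ_id: str
    contig: str
    genomic_start: int
    genomic_end: int
    sequence: str

    @property
    def circ_length(self) -> int:
        return self.genomic_end - self.genomic_start

    @property
    def junction_offset(self) -> int:
        """Pseudo-reference position of the BSJ (pad begins here)."""
        return self.circ_length

    @property
    def pad_length(self) -> int:
        return len(self.sequence) - self.circ_length

    def project(self, pos: int) -> int:
        """Map a pseudo-reference position to its genomic position."""
        if not 0 <= pos < len(self.sequence):
            raise IndexError(f"pseudo position {pos} outside [0,{len(self.sequence)})")
        if pos < self.circ_length:
            return self.genomic_start + pos
        return self.genomic_start + (pos - self.circ_length)

    def project_span(self, start: int, end: int) -> list[tuple[int, int]]:
        """Genomic blocks for pseudo span [start, end), split at the junction."""
        if start >= end:
            raise ValueError("empty span")
        L = self.circ_length
        if end <= L or start >= L:
            return [(self.project(start), self.project(end - 1) + 1)]
        return [
            (self.genomic_start + start, self.genomic_end),
            (self.genomic_start, self.genomic_start + (end - L)),
        ]


def build_pseudo_reference(circ: CircCall, genome: Genome, readlen: int) -> PseudoRef:
    """Rotated circular reference: the circle span plus a readlen-1 pad."""
    if readlen < 1:
        raise ValueError("readlen must be >= 1")
    iv = circ.interval
    if len(iv) < MIN_CIRC_LENGTH:
        raise ValueError(
            f"{circ.circ_id}: circle span {len(iv)} nt is below the "
            f"{MIN_CIRC_LENGTH} nt minimum for alignment"
        )
    span = genome.fetch(Interval(iv.contig, iv.start, iv.end, "+"))
    pad = min(readlen - 1, len(span))
    return PseudoRef(circ.circ_id, iv.contig, iv.start, iv.end, span + span[:pad])


def extract_bsj_read_pairs(
    circ: CircCall, reads: dict[str, tuple[str, str]]
) -> list[tuple[str, str, str]]:
    """Pull both mates of every pair named in the call's BSJ read ids.

    Returns (read id, mate1 seq, mate2 seq) triples; ids missing from
    the read store are skipped with a warning.
    """
    if not circ.read_ids:
        log.warning("%s: no BSJ read ids listed; circ dropped", circ.circ_id)
        return []
    out = []
    for rid in circ.read_ids:
        pair = reads.get(rid)
        if pair is None:
            log.warning("%s: BSJ read %s absent from input; pair skipped",
                        circ.circ_id, rid)
            continue
        out.append((rid, pair[0], pair[1]))
    return out


@dataclass
class PlacedMate:
    start: int  # pseudo-reference coordinates of the ALIGNED part
    end: int
    is_reverse: bool
    mismatches: int
    clipped: int = 0  # read bases outside the aligned part

    @property
    def aligned_length(self) -> int:
        return self.end - self.start


@dataclass
class PlacementConfig:
    seed_k: int = 20
    max_mismatch_rate: float = 0.05
    min_aligned: int = 30
    xdrop: int = 8  # extension stops when score falls this far below its max


def _extend(query: str, ref: str, cand: int, off: int, k: int,
            xdrop: int) -> tuple[int, int, int]:
    """X-drop ungapped extension around a seed; returns (q0, q1, mismatches).

    Bases beyond the extension stop are soft-clipped — this is what lets
    reads that run off a splice junction or the back-splice pad still
    anchor their matching part.
    """
    n = len(query)

    def matches(i: int) -> bool:
        p = cand + i
        return 0 <= p < len(ref) and query[i] == ref[p]

    # right of the seed
    best = score = 0
    q1, mm_r, mm = off + k, 0, 0
    for i in range(off + k, n):
        if cand + i >= len(ref):
            break
        score += 1 if matches(i) else -3
        mm += 0 if matches(i) else 1
        if score > best:
            best, q1, mm_r = score, i + 1, mm
        elif best - score > xdrop:
            break
    # left of the seed
    best = score = 0
    q0, mm_l, mm = off, 0, 0
    for i in range(off - 1, -1, -1):
        if cand + i < 0:
            break
        score += 1 if matches(i) else -3
        mm += 0 if matches(i) else 1
        if score > best:
            best, q0, mm_l = score, i, mm
        elif best - score > xdrop:
            break
    return q0, q1, mm_l + mm_r


def _place_mate(seq: str, pseudo: PseudoRef, cfg: PlacementConfig,
                index: dict[str, list[int]]) -> PlacedMate | None:
    """Unique best placement of one mate, trying both orientations.

    Exact k-mer seeds anchor candidate positions; ungapped X-drop
    extension soft-clips read tails that leave the pseudo-reference or
    cross a spliced-out junction. Returns None when the read does not
    place (no seed, too short an aligned part, too many mismatches) or
    places ambiguously (distinct positions with equal best score).
    """
    ref = pseudo.sequence
    k = cfg.seed_k
    hits: dict[tuple[int, bool], tuple[int, int, int]] = {}
    for rc in (False, True):
        query = reverse_complement(seq) if rc else seq
        if len(query) < k:
            continue
        seen: set[tuple[int, int]] = set()
        for off in range(0, len(query) - k + 1, k):
            for hit in index.get(query[off : off + k], ()):
                cand = hit - off
                if (cand, rc) in seen:
                    continue
                seen.add((cand, rc))
                q0, q1, mm = _extend(query, ref, cand, off, k, cfg.xdrop)
                aligned = q1 - q0
                if aligned < cfg.min_aligned:
                    continue
                if mm > cfg.max_mismatch_rate * aligned:
                    continue
                prev = hits.get((cand, rc))
                if prev is None or (q1 - q0) - mm > (prev[1] - prev[0]) - prev[2]:
                    hits[(cand, rc)] = (q0, q1, mm)
    if not hits:
        return None
    def quality(item):
        (cand, rc), (q0, q1, mm) = item
        return (q1 - q0) - 3 * mm
    best_q = max(quality(it) for it in hits.items())
    winners = [it for it in hits.items() if quality(it) == best_q]
    starts = {(cand + q0, rc) for (cand, rc), (q0, _, _) in winners}
    if len(starts) != 1:
        return None  # ambiguous placement
    (cand, rc), (q0, q1, mm) = winners[0]
    return PlacedMate(cand + q0, cand + q1, rc, mm, len(seq) - (q1 - q0))


def kmer_index(sequence: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(sequence) - k + 1):
        idx.setdefault(sequence[i : i + k], []).append(i)
    return idx


@dataclass
class PlacedPair:
    read_id: str
    mate1: PlacedMate
    mate2: PlacedMate


def place_pair(
    read_id: str, seq1: str, seq2: str, pseudo: PseudoRef,
    config: PlacementConfig | None = None,
    index: dict[str, list[int]] | None = None,
) -> PlacedPair | None:
    """Place both mates on the pseudo-reference; require FR orientation.

    On a circular template mate order is rotationally ambiguous, so only
    opposite orientations are enforced, not left/right order.
    """
    cfg = config or PlacementConfig()
    if index is None:
        index = kmer_index(pseudo.sequence, cfg.seed_k)
    m1 = _place_mate(seq1, pseudo, cfg, index)
    m2 = _place_mate(seq2, pseudo, cfg, index)
    if m1 is None or m2 is None:
        return None
    if m1.is_reverse == m2.is_reverse:
        return None
    return PlacedPair(read_id, m1, m2)


CATEGORIES = ("intronic", "exon_intron_junction", "exonic_only", "unplaced")


@dataclass
class PairEvidence:
    circ_id: str
    read_id: str
    category: str
    supporting_introns: list[IntronInterval] = field(default_factory=list)
    crosses_bsj: bool = False


def _mate_blocks(mate: PlacedMate, pseudo: PseudoRef) -> list[tuple[int, int]]:
    return pseudo.project_span(mate.start, mate.end)


def classify_pair(
    pair: PlacedPair,
    pseudo: PseudoRef,
    introns: list[IntronInterval],
    overhang: int = 5,
) -> PairEvidence:
    """Classify a placed pair by its intronic evidence.

    ``intronic`` — some mate's aligned bases fall entirely inside one
    intron; ``exon_intron_junction`` — some mate's aligned block crosses
    an intron boundary with at least ``overhang`` bases on both sides;
    ``exonic_only`` otherwise. Symmetric in the two mates.
    """
    intronic_hits: dict[tuple, IntronInterval] = {}
    junction_hits: dict[tuple, IntronInterval] = {}
    crosses = False
    for mate in (pair.mate1, pair.mate2):
        if mate.start < pseudo.junction_offset < mate.end:
            crosses = True
        blocks = _mate_blocks(mate, pseudo)
        for intron in introns:
            iv = intron.interval
            if all(b0 >= iv.start and b1 <= iv.end for b0, b1 in blocks):
                intronic_hits.setdefault(intron.key, intron)
            for b0, b1 in blocks:
                for boundary in (iv.start, iv.end):
                    if b0 <= boundary - overhang and b1 >= boundary + overhang:
                        junction_hits.setdefault(intron.key, intron)
    if intronic_hits:
        return PairEvidence(pseudo.circ_id, pair.read_id, "intronic",
                            sorted(intronic_hits.values(), key=lambda i: i.key),
                            crosses)
    if junction_hits:
        return PairEvidence(pseudo.circ_id, pair.read_id, "exon_intron_junction",
                            sorted(junction_hits.values(), key=lambda i: i.key),
                            crosses)
    return PairEvidence(pseudo.circ_id, pair.read_id, "exonic_only", [], crosses)


@dataclass
class Candidate:
    circ_id: str
    intron: IntronInterval
    support: int
    read_ids: list[str]


def candidate_eicirnas(
    calls: list[CircCall],
    evidence: list[PairEvidence],
    min_support: int = 1,
) -> list[Candidate]:
    """Candidate (circle, intron) pairs from intron-bearing BSJ pairs.

    Every classified pair already belongs to a BSJ-supporting fragment,
    so a candidate needs only ``min_support`` pairs whose category is
    intronic or exon_intron_junction naming the intron.
    """
    by_circ: dict[str, dict[tuple, tuple[IntronInterval, list[str]]]] = {}
    for ev in evidence:
        if ev.category not in ("intronic", "exon_intron_junction"):
            continue
        bucket = by_circ.setdefault(ev.circ_id, {})
        for intron in ev.supporting_introns:
            entry = bucket.setdefault(intron.key, (intron, []))
            entry[1].append(ev.read_id)
    out: list[Candidate] = []
    for call in calls:
        for intron, rids in by_circ.get(call.circ_id, {}).values():
            rids = sorted(set(rids))
            if len(rids) >= min_support:
                out.append(Candidate(call.circ_id, intron, len(rids), rids))
    return out


def write_diagnostics(evidence: list[PairEvidence], path: str | Path) -> None:
    from collections import Counter

    per_circ: dict[str, Counter] = {}
    for ev in evidence:
        per_circ.setdefault(ev.circ_id, Counter())[ev.category] += 1
    with open(path, "w") as fh:
        fh.write("circ_id\tintronic\texon_intron_junction\texonic_only\tunplaced\n")
        for circ_id in sorted(per_circ):
            c = per_circ[circ_id]
            fh.write(
                f"{circ_id}\t{c['intronic']}\t{c['exon_intron_junction']}"
                f"\t{c['exonic_only']}\t{c['unplaced']}\n"
            )
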