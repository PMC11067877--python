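"""Naive per-read, per-base reference implementations used as test oracles.

Deliberately slow and structured differently from the package: metrics
are re-derived from the set of aligned reference positions of each read,
walked base by base from the CIGAR.
"""
from __future__ import annotations

from eicirna.model import AlignedRead, IntronInterval


def aligned_positions(read: AlignedRead) -> tuple[list[int], list[tuple[int, int]]]:
    """(sorted aligned reference positions, N-gap intervals) by CIGAR walk."""
    pos = read.start
    aligned: list[int] = []
    gaps: list[tuple[int, int]] = []
    for op, n in read.cigar:
        if op in "M=XD":
            for _ in range(n):
                aligned.append(pos)
                pos += 1
        elif op == "N":
            gaps.append((pos, pos + n))
            pos += n
        # I/S/H: no reference
    return aligned, gaps


def runs(positions: list[int]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive positions as half-open intervals."""
    if not positions:
        return []
    out = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p != prev + 1:
            out.append((start, prev + 1))
            start = p
        prev = p
    out.append((start, prev + 1))
    return out


def naive_metrics(
    reads: list[AlignedRead], intron: IntronInterval, overhang: int = 5
) -> tuple[int, int, int, int, float]:
    """(EE, EI, IE, I, IC) recomputed naively."""
    iv = intron.interval
    ee = ei = ie = i_count = 0
    covered: set[int] = set()
    w_len = min(200, len(iv))
    w0 = iv.start + (len(iv) - w_len) // 2
    w1 = w0 + w_len
    for read in reads:
        aligned, gaps = aligned_positions(read)
        aligned_set = set(aligned)
        covered.update(p for p in aligned if iv.start <= p < iv.end)

        is_ee = False
        for g0, g1 in gaps:
            if (g0, g1) == (iv.start, iv.end):
                left = 0
                p = g0 - 1
                while p in aligned_set:
                    left += 1
                    p -= 1
                right = 0
                p = g1
                while p in aligned_set:
                    right += 1
                    p += 1
                if left >= overhang and right >= overhang:
                    is_ee = True
        if is_ee:
            ee += 1
        else:
            if all(p in aligned_set
                   for p in range(iv.start - overhang, iv.start + overhang)):
                ei += 1
            if all(p in aligned_set
                   for p in range(iv.end - overhang, iv.end + overhang)):
                ie += 1

        read_runs = runs(aligned)
        touching = [r for r in read_runs if r[0] < iv.end and r[1] > iv.start]
        if touching and all(r0 >= iv.start and r1 <= iv.end for r0, r1 in touching):
            if any(r0 < w1 and r1 > w0 for r0, r1 in touching):
                i_count += 1
    ic = len(covered) / len(iv)
    return ee, ei, ie, i_count, ic


def random_reads_near_intron(rng, intron: IntronInterval, n: int) -> list[AlignedRead]:
    """Random mix of contiguous, spliced and clipped reads around an intron."""
    iv = intron.interval
    reads = []
    for j in range(n):
        kind = rng.integers(0, 4)
        if kind == 0:  # contiguous read somewhere near the intron
            start = int(rng.integers(max(0, iv.start - 200), iv.end + 200))
            length = int(rng.integers(20, 160))
            cigar = [("M", length)]
        elif kind == 1:  # spliced exactly over the intron
            left = int(rng.integers(1, 40))
            right = int(rng.integers(1, 40))
            start = iv.start - left
            cigar = [("M", left), ("N", len(iv)), ("M", right)]
        elif kind == 2:  # spliced with a near-miss gap
            shift = int(rng.integers(-8, 9)) or 3
            left, right = int(rng.integers(5, 40)), int(rng.integers(5, 40))
            start = max(0, iv.start + shift - left)
            gap = max(10, len(iv) + int(rng.integers(-10, 11)))
            cigar = [("M", left), ("N", gap), ("M", right)]
        else:  # soft-clipped contiguous read
            start = int(rng.integers(max(0, iv.start - 100), iv.end + 100))
            cigar = [("S", 10), ("M", int(rng.integers(20, 120))), ("S", 5)]
        reads.append(AlignedRead(f"r{j}", 1, iv.contig, start, cigar))
    return reads
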