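import numpy as np
import pytest

from eicirna import evidence as ev
from eicirna.model import CircCall, Genome, Interval, IntronInterval, reverse_complement


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(11)
    return Genome({"chrT": "".join(rng.choice(list("ACGT"), size=2000))})


def circ(start=100, end=900, cid="c1", count=5, read_ids=()):
    return CircCall(cid, Interval("chrT", start, end, "+"), count, "exon",
                    list(read_ids))


INTRONS = [
    IntronInterval(Interval("chrT", 250, 400, "+"), "tx1", 1),
    IntronInterval(Interval("chrT", 550, 700, "+"), "tx1", 2),
]


@pytest.fixture(scope="module")
def pseudo(genome):
    return ev.build_pseudo_reference(circ(), genome, readlen=150)


class TestPseudoRef:
    def test_length_and_junction(self, pseudo):
        assert pseudo.circ_length == 800
        assert len(pseudo.sequence) == 949
        assert pseudo.junction_offset == 800

    def test_short_circle_pad_truncated(self, genome):
        p = ev.build_pseudo_reference(circ(100, 200), genome, readlen=150)
        assert len(p.sequence) == 200 and p.pad_length == 100

    def test_tiny_circle_refused(self, genome):
        with pytest.raises(ValueError, match="minimum"):
            ev.build_pseudo_reference(circ(100, 115), genome, readlen=150)

    def test_rotation_identity(self, pseudo):
        assert pseudo.project(pseudo.junction_offset) == 100
        assert pseudo.project(0) == 100
        assert pseudo.project(799) == 899

    def test_pad_sequence_matches_prefix(self, pseudo):
        assert pseudo.sequence[800:] == pseudo.sequence[:149]

    def test_projection_bijective_outside_pad(self, pseudo):
        seen = {pseudo.project(p) for p in range(pseudo.circ_length)}
        assert len(seen) == pseudo.circ_length

    def test_project_span_wraps(self, pseudo):
        blocks = pseudo.project_span(780, 830)
        assert blocks == [(880, 900), (100, 130)]


class TestPlacement:
    def test_verbatim_read_placed(self, pseudo):
        read = pseudo.sequence[300:400]
        m = ev._place_mate(read, pseudo, ev.PlacementConfig(),
                           ev.kmer_index(pseudo.sequence, 20))
        assert m is not None and (m.start, m.end) == (300, 400)
        assert m.mismatches == 0 and not m.is_reverse

    def test_reverse_complement_read_placed(self, pseudo):
        read = reverse_complement(pseudo.sequence[300:400])
        m = ev._place_mate(read, pseudo, ev.PlacementConfig(),
                           ev.kmer_index(pseudo.sequence, 20))
        assert m is not None and m.is_reverse and m.start == 300

    def test_mismatches_at_threshold(self, pseudo):
        rng = np.random.default_rng(3)
        read = list(pseudo.sequence[500:600])
        for i in rng.choice(100, size=4, replace=False):  # 4% < 5% cap
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        m = ev._place_mate("".join(read), pseudo, ev.PlacementConfig(),
                           ev.kmer_index(pseudo.sequence, 20))
        assert m is not None and m.start == 500 and m.mismatches == 4

    def test_unrelated_read_unplaced(self, pseudo):
        rng = np.random.default_rng(4)
        junk = "".join(rng.choice(list("ACGT"), size=100))
        m = ev._place_mate(junk, pseudo, ev.PlacementConfig(),
                           ev.kmer_index(pseudo.sequence, 20))
        assert m is None

    def test_pair_requires_opposite_orientation(self, pseudo):
        s1 = pseudo.sequence[100:250]
        s2 = pseudo.sequence[300:450]
        assert ev.place_pair("r", s1, s2, pseudo) is None
        assert ev.place_pair("r", s1, reverse_complement(s2), pseudo) is not None

    def test_circular_reads_place_reliably_with_errors(self, genome):
        """Rotated reads at 1% error place with probability >= 0.99."""
        c = circ()
        pseudo = ev.build_pseudo_reference(c, genome, readlen=150)
        circle = genome.fetch(Interval("chrT", 100, 900, "+"))
        doubled = circle * 2
        rng = np.random.default_rng(5)
        placed = 0
        n = 1000
        index = ev.kmer_index(pseudo.sequence, 20)
        for _ in range(n):
            s = int(rng.integers(0, 800))
            read = list(doubled[s : s + 150])
            errs = np.flatnonzero(rng.random(150) < 0.01)
            for i in errs:
                read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
            m = ev._place_mate("".join(read), pseudo, ev.PlacementConfig(), index)
            # placed correctly: aligned part sits inside the true span
            # (end-mismatches may be soft-clipped)
            placed += (m is not None and m.start >= s and m.end <= s + 150
                       and m.aligned_length >= 100)
        assert placed / n >= 0.99


def _pair(m1: ev.PlacedMate, m2: ev.PlacedMate, rid="r1"):
    return ev.PlacedPair(rid, m1, m2)


def _mate(start, end, reverse=False):
    return ev.PlacedMate(start, end, reverse, 0)


class TestClassify:
    def test_fully_intronic(self, pseudo):
        # genomic [260, 380) = pseudo [160, 280), inside intron 1
        pair = _pair(_mate(160, 280), _mate(0, 100, True))
        out = ev.classify_pair(pair, pseudo, INTRONS)
        assert out.category == "intronic"
        assert [i.ordinal for i in out.supporting_introns] == [1]

    def test_junction_with_five_base_overhang(self, pseudo):
        # genomic [220, 255): 30 exonic + 5 intronic at boundary 250
        pair = _pair(_mate(120, 155), _mate(0, 100, True))
        out = ev.classify_pair(pair, pseudo, INTRONS, overhang=5)
        assert out.category == "exon_intron_junction"

    def test_four_base_overhang_rejected(self, pseudo):
        pair = _pair(_mate(120, 154), _mate(0, 100, True))
        out = ev.classify_pair(pair, pseudo, INTRONS, overhang=5)
        assert out.category == "exonic_only"

    def test_mate_swap_invariance(self, pseudo):
        m_int, m_ex = _mate(160, 280), _mate(0, 100, True)
        a = ev.classify_pair(_pair(m_int, m_ex), pseudo, INTRONS)
        b = ev.classify_pair(_pair(m_ex, m_int), pseudo, INTRONS)
        assert a.category == b.category == "intronic"

    def test_crosses_bsj_flag(self, pseudo):
        pair = _pair(_mate(780, 830), _mate(0, 100, True))
        out = ev.classify_pair(pair, pseudo, INTRONS)
        assert out.crosses_bsj and out.category == "exonic_only"


class TestCandidates:
    def test_counting_rule(self):
        calls = [circ(cid="circA")]
        evidence = [
            ev.PairEvidence("circA", "r1", "intronic", [INTRONS[0]], True),
            ev.PairEvidence("circA", "r2", "exon_intron_junction", [INTRONS[0]], False),
            ev.PairEvidence("circA", "r3", "exonic_only", [], True),
        ]
        cands = ev.candidate_eicirnas(calls, evidence)
        assert len(cands) == 1
        assert cands[0].support == 2 and cands[0].intron.ordinal == 1

    def test_exonic_only_never_candidates(self):
        calls = [circ(cid="circA")]
        evidence = [ev.PairEvidence("circA", "r1", "exonic_only", [], True)]
        assert ev.candidate_eicirnas(calls, evidence) == []

    def test_min_support_threshold(self):
        calls = [circ(cid="circA")]
        evidence = [ev.PairEvidence("circA", "r1", "intronic", [INTRONS[0]], True)]
        assert len(ev.candidate_eicirnas(calls, evidence, min_support=1)) == 1
        assert ev.candidate_eicirnas(calls, evidence, min_support=2) == []


class TestExtractPairs:
    def test_listed_ids_recovered(self):
        reads = {"a": ("AC", "GT"), "b": ("CC", "GG")}
        c = circ(read_ids=["a", "b"])
        assert len(ev.extract_bsj_read_pairs(c, reads)) == 2

    def test_missing_id_skipped(self):
        c = circ(read_ids=["a", "zz"])
        out = ev.extract_bsj_read_pairs(c, {"a": ("AC", "GT")})
        assert [rid for rid, _, _ in out] == ["a"]

    def test_empty_id_list(self):
        assert ev.extract_bsj_read_pairs(circ(), {}) == []
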