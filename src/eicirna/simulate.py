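"""Synthetic fixtures: toy genomes, paired-end read simulation, truth tables.

The simulator emulates the library designs the detection pipeline is
aimed at: paired-end reads (default 2 x 150 nt) from fragments around
300 +/- 30 nt (i.e. above the 250 nt the method needs to see past a
back-splice junction into an intron), drawn from three template kinds:

* ``linear`` — the spliced mRNA of a transcript;
* ``ecirc``  — an exonic circRNA: the spliced exons circularized;
* ``eici``   — an exon-intron circRNA: circularized exons with one
  annotated intron retained.

Fragments on circular templates may wrap the back-splice junction.
Reads carry uniform substitution errors and constant Phred-30 quality.
Alongside FASTQ the simulator emits a SAM against the toy genome
(splice-aware by construction: spliced-out introns become N operations,
and the arm of a BSJ-crossing read that cannot be represented linearly
is soft-clipped), a CIRI2-format truth BSJ table, and a per-fragment
truth table linking every read to its source molecule.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CircCall,
    Genome,
    Interval,
    IntronInterval,
    Transcript,
    TranscriptCatalog,
    reverse_complement,
)

DEFAULT_READ_LENGTH = 150
DEFAULT_FRAGMENT_MEAN = 300.0
DEFAULT_FRAGMENT_SD = 30.0
DEFAULT_ERROR_RATE = 0.005
PHRED_CHAR = "?"  # constant Phred 30

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------- toy genome

@dataclass
class GeneSpec:
    gene_id: str
    exon_lengths: list[int]
    intron_lengths: list[int]
    strand: str = "+"
    start: int | None = None  # explicit placement; sequential otherwise

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != max(0, len(self.exon_lengths) - 1):
            raise ValueError(
                f"{self.gene_id}: need exactly n_exons-1 intron lengths"
            )
        if any(l < 1 for l in self.exon_lengths):
            raise ValueError(f"{self.gene_id}: exon length < 1")
        if any(l < 1 for l in self.intron_lengths):
            raise ValueError(f"{self.gene_id}: intron length < 1")

    @property
    def span(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)


def make_toy_genome(
    genes: list[GeneSpec],
    seed: int,
    contig: str = "chrT",
    spacer: int = 500,
) -> tuple[Genome, TranscriptCatalog]:
    """Random toy genome with planted canonical GT..AG intron boundaries.

    Genes are laid out left to right with ``spacer`` nt between them
    unless explicit starts are given; overlapping placements are an
    error. Each gene yields one transcript (id ``<gene>.t1``).
    """
    rng = np.random.default_rng(seed)
    placements: list[tuple[int, GeneSpec]] = []
    cursor = spacer
    for g in genes:
        start = g.start if g.start is not None else cursor
        placements.append((start, g))
        cursor = start + g.span + spacer
    placements_sorted = sorted(placements, key=lambda p: p[0])
    for (s1, g1), (s2, g2) in zip(placements_sorted, placements_sorted[1:]):
        if s2 < s1 + g1.span:
            raise ValueError(f"genes {g1.gene_id} and {g2.gene_id} overlap")
    total = max(s + g.span for s, g in placements) + spacer
    seq = rng.choice(_BASES, size=total)

    catalog = TranscriptCatalog()
    for start, g in placements:
        exons: list[Interval] = []
        pos = start
        for i, elen in enumerate(g.exon_lengths):
            exons.append(Interval(contig, pos, pos + elen, g.strand))
            pos += elen
            if i < len(g.intron_lengths):
                ilen = g.intron_lengths[i]
                istart, iend = pos, pos + ilen
                if ilen >= 4:  # plant canonical splice dinucleotides
                    if g.strand != "-":
                        seq[istart:istart + 2] = [b"G", b"T"]
                        seq[iend - 2:iend] = [b"A", b"G"]
                    else:
                        seq[istart:istart + 2] = [b"C", b"T"]
                        seq[iend - 2:iend] = [b"A", b"C"]
                pos = iend
        catalog.add(Transcript(f"{g.gene_id}.t1", g.gene_id, g.strand, exons))
    genome = Genome({contig: seq.tobytes().decode()})
    return genome, catalog


# ----------------------------------------------------------------- templates

TEMPLATE_TYPES = ("linear", "ecirc", "eici")


@dataclass
class TemplateSpec:
    template_id: str
    ttype: str
    transcript_id: str
    retained_intron_ordinal: int | None = None
    depth: float = 50.0

    def __post_init__(self) -> None:
        if self.ttype not in TEMPLATE_TYPES:
            raise ValueError(f"bad template type {self.ttype!r}")
        if self.ttype == "eici" and self.retained_intron_ordinal is None:
            raise ValueError(f"{self.template_id}: eici needs a retained intron")
        if self.depth < 0:
            raise ValueError("negative depth")


@dataclass
class Template:
    template_id: str
    ttype: str
    blocks: list[tuple[int, int]]  # genomic, ascending, merged when abutting
    contig: str
    circular: bool
    sequence: str
    retained_intron: IntronInterval | None = None
    circ_interval: Interval | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    def retained_span(self) -> tuple[int, int] | None:
        """Template coordinates of the retained intron, if any."""
        if self.retained_intron is None:
            return None
        iv = self.retained_intron.interval
        off = 0
        for b0, b1 in self.blocks:
            if b0 <= iv.start and iv.end <= b1:
                return off + (iv.start - b0), off + (iv.end - b0)
            off += b1 - b0
        return None

    def to_genomic(self, a: int, b: int) -> list[tuple[int, int]]:
        """Genomic blocks for non-wrapping template span [a, b)."""
        if not 0 <= a < b <= self.length:
            raise ValueError(f"bad template span [{a},{b})")
        out = []
        off = 0
        for b0, b1 in self.blocks:
            blen = b1 - b0
            lo, hi = max(a, off), min(b, off + blen)
            if hi > lo:
                out.append((b0 + (lo - off), b0 + (hi - off)))
            off += blen
        return out


def _merge_abutting(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged = [blocks[0]]
    for b0, b1 in blocks[1:]:
        if b0 == merged[-1][1]:
            merged[-1] = (merged[-1][0], b1)
        else:
            merged.append((b0, b1))
    return merged


def build_template(
    spec: TemplateSpec, catalog: TranscriptCatalog, genome: Genome
) -> Template:
    t = catalog.get(spec.transcript_id)
    blocks = [(e.start, e.end) for e in t.exons]
    retained = None
    if spec.ttype == "eici":
        introns = {i.ordinal: i for i in t.introns()}
        if spec.retained_intron_ordinal not in introns:
            raise ValueError(
                f"{spec.template_id}: transcript {t.transcript_id} has no "
                f"intron ordinal {spec.retained_intron_ordinal}"
            )
        retained = introns[spec.retained_intron_ordinal]
        iv = retained.interval
        blocks = sorted(blocks + [(iv.start, iv.end)])
    blocks = _merge_abutting(blocks)
    seq = "".join(
        genome.fetch(Interval(t.contig, b0, b1, "+")) for b0, b1 in blocks
    )
    circular = spec.ttype in ("ecirc", "eici")
    circ_iv = Interval(t.contig, t.start, t.end, t.strand) if circular else None
    return Template(spec.template_id, spec.ttype, blocks, t.contig,
                    circular, seq, retained, circ_iv)


# ----------------------------------------------------------------- sim config

@dataclass
class SimConfig:
    seed: int
    templates: list[TemplateSpec]
    read_length: int = DEFAULT_READ_LENGTH
    fragment_mean: float = DEFAULT_FRAGMENT_MEAN
    fragment_sd: float = DEFAULT_FRAGMENT_SD
    error_rate: float = DEFAULT_ERROR_RATE

    def __post_init__(self) -> None:
        if self.fragment_mean < self.read_length:
            raise ValueError(
                f"fragment mean {self.fragment_mean} below read length "
                f"{self.read_length}"
            )
        if not 0 <= self.error_rate < 1:
            raise ValueError("error rate outside [0,1)")


@dataclass
class TruthRow:
    read_id: str
    template_id: str
    template_type: str
    crosses_bsj: bool
    covers_retained_intron: bool
    fragment_length: int = 0


@dataclass
class TruthTable:
    rows: list[TruthRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def by_read(self) -> dict[str, TruthRow]:
        out = {}
        for r in self.rows:
            if r.read_id in out:
                raise ValueError(f"duplicate read id {r.read_id}")
            out[r.read_id] = r
        return out

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\ttemplate_id\ttemplate_type\tcrosses_bsj"
                     "\tcovers_retained_intron\tfragment_length\n")
            for r in self.rows:
                fh.write(
                    f"{r.read_id}\t{r.template_id}\t{r.template_type}"
                    f"\t{int(r.crosses_bsj)}\t{int(r.covers_retained_intron)}"
                    f"\t{r.fragment_length}\n"
                )


@dataclass
class SamRecord:
    qname: str
    flag: int
    contig: str
    pos: int  # 0-based
    mapq: int
    cigar: str
    seq: str
    qual: str
    pnext: int = -1  # 0-based mate position; -1 = unavailable

    def line(self) -> str:
        rnext = "=" if self.pnext >= 0 else "*"
        return "\t".join([
            self.qname, str(self.flag), self.contig, str(self.pos + 1),
            str(self.mapq), self.cigar, rnext, str(self.pnext + 1), "0",
            self.seq, self.qual,
        ])


@dataclass
class SimResult:
    reads1: list[tuple[str, str]]  # (read id, sequence)
    reads2: list[tuple[str, str]]
    truth: TruthTable
    truth_calls: list[CircCall]
    sam_records: list[SamRecord]
    contig_lengths: dict[str, int]
    templates: list[Template]

    @property
    def n_fragments(self) -> int:
        return len(self.reads1)

    def read_pairs(self) -> dict[str, tuple[str, str]]:
        r2 = dict(self.reads2)
        return {rid: (seq1, r2[rid]) for rid, seq1 in self.reads1}

    def write_fastq(self, path1: str | Path, path2: str | Path) -> None:
        for path, reads, mate in ((path1, self.reads1, 1), (path2, self.reads2, 2)):
            opener = (
                (lambda p: gzip.GzipFile(p, "wb", mtime=0))
                if str(path).endswith(".gz") else (lambda p: open(p, "wb"))
            )
            with opener(str(path)) as fh:
                for rid, seq in reads:
                    rec = f"@{rid}/{mate}\n{seq}\n+\n{PHRED_CHAR * len(seq)}\n"
                    fh.write(rec.encode())

    def write_sam(self, path: str | Path) -> None:
        recs = sorted(self.sam_records, key=lambda r: (r.contig, r.pos, r.qname, r.flag))
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:coordinate\n")
            for name, length in self.contig_lengths.items():
                fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
            for rec in recs:
                fh.write(rec.line() + "\n")

    @property
    def total_mapped_reads(self) -> int:
        return sum(1 for r in self.sam_records if not r.flag & 0x4)


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[rng.integers(0, 3)]])
    return arr.tobytes().decode()


def _sam_for_mate(
    template: Template, a: int, b: int, seq_forward: str, qname: str,
    flag: int, contig: str,
) -> SamRecord:
    """SAM record for a mate covering template span [a, b) (b may wrap).

    The longest non-wrapping run is aligned; the rest is soft-clipped —
    what a splice-aware linear aligner does with a back-splice read.
    """
    L = template.length
    if b <= L:
        runs = [(a, b, 0)]
    else:
        runs = [(a, L, 0), (0, b - L, L - a)]  # (ta, tb, offset in SEQ)
    ta, tb, q0 = max(runs, key=lambda r: r[1] - r[0])
    gblocks = template.to_genomic(ta, tb)
    cig = []
    if q0:
        cig.append(f"{q0}S")
    for i, (g0, g1) in enumerate(gblocks):
        if i:
            cig.append(f"{g0 - gblocks[i - 1][1]}N")
        cig.append(f"{g1 - g0}M")
    tail = len(seq_forward) - q0 - (tb - ta)
    if tail:
        cig.append(f"{tail}S")
    return SamRecord(qname, flag, contig, gblocks[0][0], 60, "".join(cig),
                     seq_forward, PHRED_CHAR * len(seq_forward))


def simulate_reads(
    genome: Genome, catalog: TranscriptCatalog, config: SimConfig
) -> SimResult:
    """Simulate paired-end reads from the configured templates.

    Fragment count per template is ceil(depth * L / (2 * read length)).
    Fragment lengths are Gaussian, truncated to [read length, template
    length]; on circular templates the fragment start is uniform on the
    circle and may wrap the back-splice junction.
    """
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    reads1: list[tuple[str, str]] = []
    reads2: list[tuple[str, str]] = []
    truth = TruthTable()
    sam: list[SamRecord] = []
    truth_calls: list[CircCall] = []
    templates = [build_template(s, catalog, genome) for s in config.templates]

    for spec, template in zip(config.templates, templates):
        L = template.length
        if L < rl:
            raise ValueError(f"{template.template_id}: template shorter than a read")
        n_frags = int(np.ceil(spec.depth * L / (2 * rl))) if spec.depth > 0 else 0
        crossing_ids: list[str] = []
        ret_span = template.retained_span()
        for i in range(n_frags):
            f = int(np.rint(rng.normal(config.fragment_mean, config.fragment_sd)))
            f = max(rl, min(f, L))
            if template.circular:
                s = int(rng.integers(0, L))
            else:
                s = int(rng.integers(0, L - f + 1))
            doubled = template.sequence * 2 if template.circular else template.sequence
            frag = doubled[s : s + f]
            rid = f"{template.template_id}_f{i:05d}"
            r1 = _mutate(frag[:rl], rng, config.error_rate)
            r2_forward = _mutate(frag[f - rl :], rng, config.error_rate)
            r2 = reverse_complement(r2_forward)
            reads1.append((rid, r1))
            reads2.append((rid, r2))
            crosses = template.circular and (s + f > L)
            if crosses:
                crossing_ids.append(rid)
            covers = False
            if ret_span is not None:
                i0, i1 = ret_span
                for m0, m1 in ((s, s + rl), (s + f - rl, s + f)):
                    for shift in (0, -L):
                        if m0 + shift < i1 and m1 + shift > i0:
                            covers = True
            truth.rows.append(
                TruthRow(rid, template.template_id, template.ttype, crosses,
                         covers, f)
            )
            # SAM: mate 1 forward, mate 2 reverse (FR library)
            a1, b1 = s, s + rl
            a2, b2 = s + f - rl, s + f
            if a2 >= L:
                a2, b2 = a2 - L, b2 - L
            flag1 = 0x1 | 0x2 | 0x40 | 0x20
            flag2 = 0x1 | 0x2 | 0x80 | 0x10
            rec1 = _sam_for_mate(template, a1, b1, r1, rid, flag1,
                                 template.contig)
            rec2 = _sam_for_mate(template, a2, b2, r2_forward, rid, flag2,
                                 template.contig)
            rec1.pnext, rec2.pnext = rec2.pos, rec1.pos
            sam.append(rec1)
            sam.append(rec2)
        if template.circular:
            iv = template.circ_interval
            truth_calls.append(
                CircCall(
                    circ_id=template.template_id,
                    interval=iv,
                    bsj_count=len(crossing_ids),
                    circ_type="exon",
                    read_ids=crossing_ids,
                )
            )
    contig_lengths = {
        name: genome.contig_length(name) for name in genome.contig_names()
    }
    return SimResult(reads1, reads2, truth, truth_calls, sam,
                     contig_lengths, templates)


# ------------------------------------------------------- standard scenario

def standard_scenario(
    seed: int,
    depth: float = 50.0,
    read_length: int = DEFAULT_READ_LENGTH,
    fragment_mean: float = DEFAULT_FRAGMENT_MEAN,
    fragment_sd: float = DEFAULT_FRAGMENT_SD,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> tuple[Genome, TranscriptCatalog, SimConfig]:
    """Three 5-exon genes; one EIciRNA, one EcircRNA, two linear templates.

    gene1 hosts the EIciRNA (whole transcript circularized, intron 1
    retained — adjacent to the back-splice junction, so ~300 nt
    fragments crossing the BSJ reach into it) and is also expressed
    linearly: the linear reads provide the spliced (EE) evidence that
    validation requires. gene2 hosts an EcircRNA (intron-free circle);
    gene3 is linear-only background.
    """
    genes = [
        GeneSpec("gene1", [150, 120, 180, 130, 160], [300, 350, 400, 320]),
        GeneSpec("gene2", [140, 160, 150, 170, 140], [330, 310, 360, 300]),
        GeneSpec("gene3", [160, 140, 170, 120, 150], [280, 340, 300, 330]),
    ]
    genome, catalog = make_toy_genome(genes, seed)
    config = SimConfig(
        seed=seed,
        templates=[
            TemplateSpec("eici1", "eici", "gene1.t1",
                         retained_intron_ordinal=1, depth=depth),
            TemplateSpec("ecirc1", "ecirc", "gene2.t1", depth=depth),
            TemplateSpec("lin1", "linear", "gene1.t1", depth=depth * 0.6),
            TemplateSpec("lin3", "linear", "gene3.t1", depth=depth * 0.6),
        ],
        read_length=read_length,
        fragment_mean=fragment_mean,
        fragment_sd=fragment_sd,
        error_rate=error_rate,
    )
    return genome, catalog, config


# --------------------------------------------------------- feature datasets

from .features import FEATURE_NAMES  # noqa: E402

# Class-conditional mean shifts (in units of the planted effect size):
# relative to NCI, retained introns (CIR and LIR) are shorter, higher-GC
# and have weaker splice sites; between the retained classes, CIR is
# longer, lower-GC and more 5' than LIR.
_CLASS_SHIFTS = {
    "NCI": {},
    "CIR": {
        "intron_length_log10": -1.0,
        "intron_gc": +1.0,
        "donor_ss_score": -1.0,
        "acceptor_ss_score": -1.0,
        "relative_position": -0.5,
    },
    "LIR": {
        "intron_length_log10": -2.0,
        "intron_gc": +2.0,
        "donor_ss_score": -1.0,
        "acceptor_ss_score": -1.0,
        "relative_position": +0.5,
    },
}


def make_feature_dataset(
    n_per_class: int = 600,
    effect_size: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled synthetic feature table with planted class effects.

    Features are unit-variance Gaussians; class means shift by
    ``effect_size`` (in SDs) along the directions of the real
    between-class differences. ``effect_size=0`` makes the classes
    indistinguishable.
    """
    if n_per_class < 10:
        raise ValueError("need >= 10 examples per class")
    if effect_size < 0:
        raise ValueError("effect size must be >= 0")
    rng = np.random.default_rng(seed)
    frames = []
    for label in ("NCI", "CIR", "LIR"):
        means = np.array(
            [_CLASS_SHIFTS[label].get(f, 0.0) for f in FEATURE_NAMES]
        ) * effect_size
        X = rng.normal(means, 1.0, size=(n_per_class, len(FEATURE_NAMES)))
        df = pd.DataFrame(X, columns=FEATURE_NAMES)
        df["label"] = label
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.index = [f"intron_{i:05d}" for i in range(len(out))]
    return out
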