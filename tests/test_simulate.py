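import gzip

import numpy as np
import pysam
import pytest

from eicirna import simulate as sim
from eicirna.model import Interval, reverse_complement

from conftest import alignments_from_sim


class TestToyGenome:
    def test_construction_counts(self):
        genome, catalog = sim.make_toy_genome(
            [sim.GeneSpec(f"g{i}", [100] * 5, [200] * 4) for i in range(3)], seed=1
        )
        assert len(catalog) == 3
        assert sum(len(t.exons) for t in catalog) == 15

    def test_deterministic_under_seed(self):
        genes = [sim.GeneSpec("g", [100, 100], [150])]
        g1, _ = sim.make_toy_genome(genes, seed=5)
        g2, _ = sim.make_toy_genome(genes, seed=5)
        assert g1.sequence("chrT") == g2.sequence("chrT")

    def test_zero_intron_length_rejected(self):
        with pytest.raises(ValueError):
            sim.GeneSpec("g", [100, 100], [0])

    def test_overlapping_genes_rejected(self):
        genes = [
            sim.GeneSpec("a", [100, 100], [100], start=100),
            sim.GeneSpec("b", [100, 100], [100], start=150),
        ]
        with pytest.raises(ValueError, match="overlap"):
            sim.make_toy_genome(genes, seed=0)

    def test_canonical_splice_sites_planted(self):
        genes = [sim.GeneSpec("g", [100, 100], [150])]
        genome, catalog = sim.make_toy_genome(genes, seed=5)
        intron = catalog.get("g.t1").introns()[0].interval
        seq = genome.fetch(Interval("chrT", intron.start, intron.end, "+"))
        assert seq.startswith("GT") and seq.endswith("AG")


@pytest.fixture(scope="module")
def bundle():
    genome, catalog, config = sim.standard_scenario(seed=3)
    return genome, catalog, config, sim.simulate_reads(genome, catalog, config)


class TestSimulateReads:
    def test_truth_table_unique_and_complete(self, bundle):
        *_, result = bundle
        by_read = result.truth.by_read()
        assert len(by_read) == result.n_fragments
        assert {rid for rid, _ in result.reads1} == set(by_read)

    def test_error_free_reads_realign_exactly(self):
        genome, catalog, config = sim.standard_scenario(seed=4, error_rate=0.0)
        result = sim.simulate_reads(genome, catalog, config)
        templates = {t.template_id: t for t in result.templates}
        truth = result.truth.by_read()
        r2 = dict(result.reads2)
        for rid, seq1 in result.reads1[:300]:
            t = templates[truth[rid].template_id]
            doubled = t.sequence * 2 if t.circular else t.sequence
            assert seq1 in doubled
            assert reverse_complement(r2[rid]) in doubled

    def test_fragment_length_mean_near_config(self):
        genome, catalog, _ = sim.standard_scenario(seed=6)
        config = sim.SimConfig(
            seed=6,
            templates=[sim.TemplateSpec("lin", "linear", "gene1.t1", depth=500.0)],
        )
        result = sim.simulate_reads(genome, catalog, config)
        lengths = np.array([r.fragment_length for r in result.truth.rows])
        assert lengths.size >= 1000
        sem = config.fragment_sd / np.sqrt(lengths.size)
        assert abs(lengths.mean() - config.fragment_mean) < 3 * sem + 1.0

    def test_depth_zero_yields_nothing(self):
        genome, catalog, _ = sim.standard_scenario(seed=1)
        config = sim.SimConfig(
            seed=1,
            templates=[sim.TemplateSpec("lin", "linear", "gene3.t1", depth=0.0)],
        )
        result = sim.simulate_reads(genome, catalog, config)
        assert result.n_fragments == 0 and len(result.truth) == 0

    def test_fragment_mean_below_read_length_rejected(self):
        with pytest.raises(ValueError, match="fragment mean"):
            sim.SimConfig(seed=1, templates=[], fragment_mean=100, read_length=150)

    def test_truth_bsj_calls_match_crossing_reads(self, bundle):
        *_, result = bundle
        truth = result.truth.by_read()
        for call in result.truth_calls:
            crossing = {rid for rid, row in truth.items()
                        if row.template_id == call.circ_id and row.crosses_bsj}
            assert set(call.read_ids) == crossing
            assert call.bsj_count == len(crossing)
            assert call.circ_type == "exon"

    def test_bsj_crossing_fraction_positive(self, bundle):
        *_, result = bundle
        assert all(c.bsj_count > 0 for c in result.truth_calls)

    def test_sam_parses_with_pysam_and_covers_genome(self, bundle, tmp_path):
        genome, catalog, config, result = bundle
        path = tmp_path / "a.sam"
        result.write_sam(path)
        with pysam.AlignmentFile(str(path)) as af:
            records = list(af.fetch(until_eof=True))
        assert len(records) == 2 * result.n_fragments
        L = genome.contig_length("chrT")
        for rec in records[:200]:
            assert 0 <= rec.reference_start < L
            assert rec.query_length == config.read_length

    def test_spliced_linear_reads_carry_n_gaps(self, bundle):
        genome, catalog, config, result = bundle
        truth = result.truth.by_read()
        spliced = [
            r for r in result.sam_records
            if truth[r.qname].template_type == "linear" and "N" in r.cigar
        ]
        assert spliced  # reads crossing exon-exon junctions exist
        intron_coords = {
            (i.interval.start, i.interval.end)
            for t in catalog for i in t.introns()
        }
        reads = alignments_from_sim(result)
        gapped = [g for r in reads for g in r.gaps()]
        assert gapped and all(g in intron_coords for g in gapped)


class TestFeatureDataset:
    def test_deterministic(self):
        a = sim.make_feature_dataset(30, 1.0, seed=2)
        b = sim.make_feature_dataset(30, 1.0, seed=2)
        assert a.equals(b)

    def test_zero_effect_indistinguishable(self):
        df = sim.make_feature_dataset(200, 0.0, seed=2)
        means = df.groupby("label").mean()
        assert float((means.max() - means.min()).max()) < 0.35

    def test_planted_directions(self):
        df = sim.make_feature_dataset(400, 2.0, seed=2)
        means = df.groupby("label").mean()
        # retained classes: shorter, higher GC, weaker splice sites than NCI
        for cls in ("CIR", "LIR"):
            assert means.loc[cls, "intron_length_log10"] < means.loc["NCI", "intron_length_log10"]
            assert means.loc[cls, "intron_gc"] > means.loc["NCI", "intron_gc"]
            assert means.loc[cls, "donor_ss_score"] < means.loc["NCI", "donor_ss_score"]
        # CIR vs LIR: longer, lower GC, more 5'
        assert means.loc["CIR", "intron_length_log10"] > means.loc["LIR", "intron_length_log10"]
        assert means.loc["CIR", "intron_gc"] < means.loc["LIR", "intron_gc"]
        assert means.loc["CIR", "relative_position"] < means.loc["LIR", "relative_position"]

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            sim.make_feature_dataset(30, -1.0, seed=0)

    def test_minimum_class_size(self):
        with pytest.raises(ValueError):
            sim.make_feature_dataset(5, 1.0, seed=0)


class TestFastqOutput:
    def test_gzip_output_byte_identical_across_runs(self, tmp_path):
        genome, catalog, config = sim.standard_scenario(seed=8)
        blobs = []
        for sub in ("a", "b"):
            d = tmp_path / sub
            d.mkdir()
            result = sim.simulate_reads(genome, catalog, config)
            result.write_fastq(d / "r1.fastq.gz", d / "r2.fastq.gz")
            blobs.append((d / "r1.fastq.gz").read_bytes())
        assert blobs[0] == blobs[1]

    def test_fastq_record_structure(self, tmp_path, bundle):
        *_, result = bundle
        result.write_fastq(tmp_path / "r1.fq", tmp_path / "r2.fq")
        lines = (tmp_path / "r1.fq").read_text().splitlines()
        assert lines[0].startswith("@") and lines[0].endswith("/1")
        assert set(lines[3]) == {"?"}  # constant Phred 30
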