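"""Format I/O, metadata harmonization, and IR boundary polishing."""

import warnings

import numpy as np
import pandas as pd
import pytest

from plastcov.core import Interval, PartitionError, PartitionMap, PlastomeRecord
from plastcov.genome_io import (
    correct_ir_boundaries,
    harmonize_label,
    parse_metadata,
    read_depth_table,
    read_plastome,
    read_results_table,
    write_depth_table,
    write_plastome,
    write_results_table,
)
from plastcov.simulate import simulate_plastome


def _write_genbank(record, path):
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord
    sr = SeqRecord(Seq(record.sequence), id=record.sample_id,
                   annotations={"molecule_type": "DNA"})
    for name in ("LSC", "IRb", "SSC", "IRa"):
        iv = record.partition_map[name]
        sr.features.append(SeqFeature(SimpleLocation(iv.start - 1, iv.end),
                                      type="misc_feature",
                                      qualifiers={"note": [name]}))
    for g in record.genes:
        strand = 1 if g.strand == "+" else -1
        iv = g.intervals[0]
        sr.features.append(SeqFeature(
            SimpleLocation(iv.start - 1, iv.end, strand=strand),
            type="gene", qualifiers={"gene": [g.name]}))
    SeqIO.write(sr, str(path), "genbank")


class TestReadPlastome:
    def test_genbank_and_fasta_routes_agree(self, small_config, tmp_path):
        rec, _ = simulate_plastome(small_config, seed=1, sample_id="S1")
        _write_genbank(rec, tmp_path / "s1.gb")
        write_plastome(rec, tmp_path / "s1.fasta", tmp_path / "s1.gff3",
                       tmp_path / "s1.bed")
        via_gb = read_plastome(tmp_path / "s1.gb", sample_id="S1")
        via_fa = read_plastome(tmp_path / "s1.fasta",
                               gff3_path=tmp_path / "s1.gff3",
                               partitions_bed=tmp_path / "s1.bed",
                               sample_id="S1")
        assert via_gb.partition_map == via_fa.partition_map == rec.partition_map
        assert via_gb.sequence == via_fa.sequence == rec.sequence
        assert len(via_gb.genes) == len(via_fa.genes) == len(rec.genes)

    def test_missing_partition_named_in_error(self, small_config, tmp_path):
        rec, _ = simulate_plastome(small_config, seed=2, sample_id="S2")
        write_plastome(rec, tmp_path / "s.fasta", tmp_path / "s.gff3",
                       tmp_path / "s.bed")
        bed = (tmp_path / "s.bed").read_text().splitlines()
        (tmp_path / "s.bed").write_text(
            "\n".join(l for l in bed if "\tSSC" not in l) + "\n")
        with pytest.raises(PartitionError, match="partition-incomplete: SSC"):
            read_plastome(tmp_path / "s.fasta", gff3_path=tmp_path / "s.gff3",
                          partitions_bed=tmp_path / "s.bed")

    def test_wrapping_partition_roundtrips_via_two_bed_rows(self, tmp_path):
        pm = PartitionMap(LSC=Interval(90, 40), IRb=Interval(41, 60),
                          SSC=Interval(61, 75), IRa=Interval(76, 89))
        seq = ("ACGT" * 25)[:100]
        rec = PlastomeRecord("W", seq, pm, [])
        write_plastome(rec, tmp_path / "w.fasta", tmp_path / "w.gff3",
                       tmp_path / "w.bed")
        back = read_plastome(tmp_path / "w.fasta", gff3_path=tmp_path / "w.gff3",
                             partitions_bed=tmp_path / "w.bed", sample_id="W")
        assert back.partition_map == pm


class TestDepthTable:
    def test_simple_three_rows(self, tmp_path):
        (tmp_path / "d.tsv").write_text("c1\t1\t5\nc1\t2\t5\nc1\t3\t5\n")
        prof = read_depth_table(tmp_path / "d.tsv", expected_length=3)
        assert list(prof.depths) == [5, 5, 5]

    def test_fill_missing_contract(self, tmp_path):
        (tmp_path / "d.tsv").write_text("c1\t1\t9\nc1\t3\t7\n")
        prof = read_depth_table(tmp_path / "d.tsv", expected_length=3,
                                fill_missing=True)
        assert list(prof.depths) == [9, 0, 7]
        with pytest.raises(ValueError, match="absent"):
            read_depth_table(tmp_path / "d.tsv", expected_length=3)

    def test_multiple_contigs_rejected(self, tmp_path):
        (tmp_path / "d.tsv").write_text("c1\t1\t5\nc2\t2\t5\n")
        with pytest.raises(ValueError, match="contig"):
            read_depth_table(tmp_path / "d.tsv", expected_length=3)

    def test_position_beyond_length_rejected(self, tmp_path):
        (tmp_path / "d.tsv").write_text("c1\t1\t5\nc1\t9\t5\n")
        with pytest.raises(ValueError):
            read_depth_table(tmp_path / "d.tsv", expected_length=3)

    def test_bedgraph_route(self, tmp_path):
        (tmp_path / "d.bg").write_text("c1\t0\t2\t4\nc1\t2\t5\t6\n")
        prof = read_depth_table(tmp_path / "d.bg", expected_length=5)
        assert list(prof.depths) == [4, 4, 6, 6, 6]

    def test_write_read_roundtrip(self, tmp_path, small_profile):
        write_depth_table(small_profile, tmp_path / "p.tsv")
        back = read_depth_table(tmp_path / "p.tsv",
                                expected_length=len(small_profile))
        assert (back.depths == small_profile.depths).all()


class TestIRPolish:
    @pytest.fixture
    def record(self, small_config):
        rec, _ = simulate_plastome(small_config, seed=1, sample_id="X")
        return rec

    def test_truncated_irb_start_recovered(self, record):
        pm = record.partition_map
        bad = PartitionMap(LSC=Interval(1, pm.LSC.end + 12),
                           IRb=Interval(pm.IRb.start + 12, pm.IRb.end),
                           SSC=pm.SSC, IRa=pm.IRa)
        polished, report = correct_ir_boundaries(
            PlastomeRecord("X", record.sequence, bad, []))
        assert report.shifts["irb_start"] == 12
        assert polished.partition_map == pm
        L = len(record)
        assert (polished.partition_map.IRb.length(L)
                == polished.partition_map.IRa.length(L))

    def test_overextended_ira_contracted(self, record):
        pm = record.partition_map
        bad = PartitionMap(LSC=pm.LSC, IRb=pm.IRb,
                           SSC=Interval(pm.SSC.start, pm.SSC.end - 7),
                           IRa=Interval(pm.IRa.start - 7, pm.IRa.end))
        polished, report = correct_ir_boundaries(
            PlastomeRecord("X", record.sequence, bad, []))
        assert report.shifts["ira_start"] == -7
        assert polished.partition_map == pm

    def test_exact_annotation_is_fixed_point(self, record):
        polished, report = correct_ir_boundaries(record)
        assert all(v == 0 for v in report.shifts.values())
        assert polished.partition_map == record.partition_map

    def test_idempotent(self, record):
        pm = record.partition_map
        bad = PartitionMap(LSC=Interval(1, pm.LSC.end + 5),
                           IRb=Interval(pm.IRb.start + 5, pm.IRb.end),
                           SSC=pm.SSC, IRa=pm.IRa)
        once, _ = correct_ir_boundaries(PlastomeRecord("X", record.sequence, bad, []))
        twice, rep2 = correct_ir_boundaries(once)
        assert twice.partition_map == once.partition_map
        assert all(v == 0 for v in rep2.shifts.values())

    def test_tandem_irs_unpolishable(self, record):
        pm = record.partition_map
        irb_seq = record.extract(pm.IRb)
        tandem = record.sequence[:pm.IRa.start - 1] + irb_seq  # IRa = forward copy
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            polished, report = correct_ir_boundaries(
                PlastomeRecord("T", tandem, pm, []))
        assert not report.polished and report.reason == "IR-unpolishable"
        assert polished.partition_map == pm
        assert any("IR-unpolishable" in str(w.message) for w in caught)


class TestMetadata:
    def test_harmonization_examples(self):
        assert harmonize_label("illumina hiseq 2500") == "HiSeq 2500"
        assert harmonize_label("  Illumina   MiSeq ") == "MiSeq"
        assert harmonize_label("") == "missing"
        assert harmonize_label("SomeNovelPlatform") == "SomeNovelPlatform"

    def test_parse_metadata_roundtrip(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "sample_id\tplatform\tsoftware\tavg_read_length\n"
            "S1\tillumina hiseq 2500\tvelvet\t150\n"
            "S2\tMiSeq\t\t\n")
        meta = parse_metadata(tmp_path / "m.tsv")
        assert meta[0].platform == "HiSeq 2500" and meta[0].software == "Velvet"
        assert meta[1].software == "missing"
        assert meta[1].avg_read_length is None

    def test_duplicate_sample_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "sample_id\tplatform\tsoftware\tavg_read_length\n"
            "S1\tMiSeq\t\t100\nS1\tMiSeq\t\t100\n")
        with pytest.raises(ValueError, match="duplicate"):
            parse_metadata(tmp_path / "m.tsv")

    def test_negative_read_length_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "sample_id\tplatform\tsoftware\tavg_read_length\n"
            "S1\tMiSeq\t\t-30\n")
        with pytest.raises(ValueError, match="positive"):
            parse_metadata(tmp_path / "m.tsv")


class TestResultsTable:
    def test_numeric_roundtrip_12_significant_digits(self, tmp_path):
        df = pd.DataFrame({"i": [1, 2, 3],
                           "x": [0.123456789012345, 1e-7, 9.87654321e8]})
        write_results_table(df, tmp_path / "r.tsv", seed=42)
        back = read_results_table(tmp_path / "r.tsv")
        assert (back["i"] == df["i"]).all()
        np.testing.assert_allclose(back["x"], df["x"], rtol=1e-11)
        header = (tmp_path / "r.tsv").read_text().splitlines()[:3]
        assert header[0].startswith("# plastcov")
        assert any("seed 42" in line for line in header)
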