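"""Reader/writer round trips and format validation."""

import pytest

from tentacle import formats
from tentacle.models import FormatError, RepeatFragment, SampleDesign, SampleInfo


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "one.fasta"
        p.write_text(">t1\nACGT\n")
        (t,) = formats.read_fasta(p)
        assert (t.id, t.sequence, t.length) == ("t1", "ACGT", 4)

    def test_lowercase_is_uppercased(self, tmp_path):
        p = tmp_path / "lc.fasta"
        p.write_text(">t1\nacgt\n")
        assert formats.read_fasta(p)[0].sequence == "ACGT"

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">t1\nACGT\n>t1\nGGGG\n")
        with pytest.raises(FormatError, match="duplicate"):
            formats.read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(FormatError, match="empty"):
            formats.read_fasta(p)

    def test_bundle_round_trip(self, bundle, tmp_path):
        """A generated transcriptome survives read -> write -> read identically."""
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        formats.write_fasta(bundle.transcripts, p1)
        again = formats.read_fasta(p1)
        formats.write_fasta(again, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert [(t.id, t.sequence) for t in again] == \
            [(t.id, t.sequence) for t in bundle.transcripts]


class TestRepeatMaskerOut:
    HEADER = "  SW  perc perc perc query begin end (left) strand repeat class/family begin end (left) ID\nscore\n\n"

    def test_plus_strand_row(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(self.HEADER +
                     " 500 10.0 0.0 0.0 t1 5 100 (900) + RTE2 LINE/RTE 10 500 (100) 1\n")
        (f,) = formats.read_repeatmasker_out(p)
        assert (f.q_begin, f.q_end) == (5, 100)
        assert (f.c_begin, f.c_end, f.c_left) == (10, 500, 100)

    def test_complement_strand_normalized(self, tmp_path):
        # on 'C' rows the consensus columns are (left) end begin
        p = tmp_path / "rm.out"
        p.write_text(self.HEADER +
                     " 500 10.0 0.0 0.0 t1 5 100 (900) C SINE1 SINE/Octo (100) 250 30 1\n")
        (f,) = formats.read_repeatmasker_out(p)
        assert f.c_begin <= f.c_end
        assert (f.c_begin, f.c_end, f.c_left) == (30, 250, 100)

    def test_class_family_parsing(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(self.HEADER +
                     " 500 10.0 0.0 0.0 t1 5 100 (900) + BovB LINE/RTE-BovB 10 500 (100) 1\n")
        (f,) = formats.read_repeatmasker_out(p)
        assert f.major_class == "LINE"
        assert f.subclass.startswith("RTE")
        assert f.summary_class == "Retroelement"

    def test_unknown_class_maps_to_unknown(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(self.HEADER +
                     " 500 10.0 0.0 0.0 t1 5 100 (900) + X Mystery/Thing 10 500 (100) 1\n")
        (f,) = formats.read_repeatmasker_out(p)
        assert f.summary_class == "Unknown"

    def test_unparsable_row_names_line(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(self.HEADER + "garbage row\n")
        with pytest.raises(FormatError, match="line 4"):
            formats.read_repeatmasker_out(p)

    def test_bundle_round_trip(self, bundle, tmp_path):
        p = tmp_path / "frags.out"
        formats.write_repeatmasker_out(bundle.fragments, p)
        again = formats.read_repeatmasker_out(p)
        assert again == bundle.fragments


class TestHitTable:
    ROW = "q1\ts1\t95.0\t100\t5\t0\t{q0}\t{q1}\t1\t100\t{ev}\t200.0\n"

    def test_ten_e_minus_five_notation(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.ROW.format(q0=1, q1=100, ev="10e-5"))
        (h,) = formats.read_hit_table(p)
        assert h.evalue == pytest.approx(1e-4)

    def test_reversed_query_coords_normalized(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.ROW.format(q0=100, q1=1, ev="1e-10"))
        (h,) = formats.read_hit_table(p)
        assert h.q_start <= h.q_end

    def test_wrong_column_count_rejected(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t95.0\n")
        with pytest.raises(FormatError, match="12 columns"):
            formats.read_hit_table(p)

    def test_bundle_round_trip(self, bundle, tmp_path):
        p = tmp_path / "hits.tsv"
        protein = [h for h in bundle.hits if h.database_tag == "protein"]
        formats.write_hit_table(protein, p)
        assert formats.read_hit_table(p, "protein") == protein


class TestIsVcf:
    def test_genotype_mapping(self, is_fixture, tmp_path):
        p = tmp_path / "is.vcf"
        design = is_fixture["design"]
        formats.write_is_vcf(is_fixture["sites"], design,
                             is_fixture["scaffold_lengths"], p)
        sites = formats.read_is_vcf(p, design)
        assert len(sites) == len(is_fixture["sites"]) == 65
        for got, want in zip(sites, is_fixture["sites"]):
            assert got.sample_presence == want.sample_presence
            assert (got.left_support, got.right_support) == \
                (want.left_support, want.right_support)
            assert got.filter_status == want.filter_status

    def test_missing_genotype_maps_to_missing(self, tmp_path):
        from tentacle.models import IntegrationSiteRecord
        design = SampleDesign(samples=[
            SampleInfo("s1", "i1", "SUB", 10), SampleInfo("s2", "i1", "GILL", 10)])
        site = IntegrationSiteRecord(
            scaffold="c1", position=100, element="RTE", filter_status="PASS",
            left_support=3, right_support=3,
            sample_presence={"s1": "present", "s2": "missing"}, site_id="x1")
        p = tmp_path / "m.vcf"
        formats.write_is_vcf([site], design, {"c1": 20_000}, p)
        (got,) = formats.read_is_vcf(p, design)
        assert got.sample_presence == {"s1": "present", "s2": "missing"}

    def test_design_mismatch_rejected(self, is_fixture, tmp_path):
        p = tmp_path / "is.vcf"
        formats.write_is_vcf(is_fixture["sites"], is_fixture["design"],
                             is_fixture["scaffold_lengths"], p)
        other = SampleDesign(samples=[SampleInfo("nope", "i1", "SUB", 10)])
        with pytest.raises(FormatError, match="do not match design"):
            formats.read_is_vcf(p, other)


class TestPlacementsGff3:
    def test_round_trip_with_blocks(self, bundle, tmp_path):
        p = tmp_path / "pl.gff3"
        formats.write_placements_gff3(bundle.placements_a, p)
        again = formats.read_placements_gff3(p)
        assert set(again) == set(bundle.placements_a)
        for tid, orig in bundle.placements_a.items():
            got = again[tid]
            assert (got.scaffold, got.strand, got.start, got.end) == \
                (orig.scaffold, orig.strand, orig.start, orig.end)
            if orig.blocks:
                assert got.blocks == orig.blocks

    def test_coverage_identity_attributes(self, tmp_path):
        p = tmp_path / "pl.gff3"
        p.write_text(
            "##gff-version 3\n"
            "scf1\tgmap\tmRNA\t1001\t2000\t.\t-\t.\tID=x;Name=t9;coverage=93.5;identity=91.0\n"
            "scf1\tgmap\texon\t1001\t2000\t.\t-\t.\tParent=x\n")
        pl = formats.read_placements_gff3(p)["t9"]
        assert pl.coverage_fraction == pytest.approx(0.935)
        assert pl.identity_fraction == pytest.approx(0.91)
        assert (pl.start, pl.end, pl.strand) == (1000, 2000, "-")


class TestCountsAndDesign:
    def test_round_trips(self, bundle, tmp_path):
        cp, dp = tmp_path / "c.tsv", tmp_path / "d.tsv"
        formats.write_counts_tsv(bundle.counts, cp)
        formats.write_design_tsv(bundle.design, dp)
        design = formats.read_design_tsv(dp)
        counts = formats.read_counts_tsv(cp, design)
        assert design == bundle.design
        assert counts.equals(bundle.counts)

    def test_negative_counts_rejected(self, tmp_path):
        p = tmp_path / "neg.tsv"
        p.write_text("transcript_id\ts1\nt1\t-3\n")
        with pytest.raises(FormatError, match="negative"):
            formats.read_counts_tsv(p)
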