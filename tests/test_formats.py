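import numpy as np
import pytest

from tissuemix import formats
from tissuemix.formats import (
    AlleleDepthRecord,
    FormatError,
    KmerHistogram,
    PileupSite,
    read_allele_depths,
    read_assignment_table,
    read_kmer_histogram,
    read_sync,
    write_assignment_table,
    write_kmer_histogram,
    write_sync,
)

TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=scf1,length=100000>
##contig=<ID=scf2,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Ref obs">
##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alt obs">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsim
scf1\t10\t.\tA\tT\t50.0\t.\t.\tGT:RO:AO\t0/1:12:8
scf1\t20\t.\tC\tG\t15.0\t.\t.\tGT:RO:AO\t0/1:10:10
scf1\t30\t.\tG\tA\t20.0\t.\t.\tGT:RO:AO\t1/1:0:25
scf1\t40\t.\tT\tC\t90.0\t.\t.\tGT:RO:AO\t1/1:1:30
scf2\t50\t.\tA\tG\t60.0\t.\t.\tGT:AD\t0/1:7,9
scf1\t60\t.\tA\tT,G\t70.0\t.\t.\tGT:RO:AO\t0/1:5,5:4
scf1\t70\t.\tAT\tA\t70.0\t.\t.\tGT:RO:AO\t0/1:5:5
scf1\t80\t.\tG\tC\t70.0\t.\t.\tGT:RO:AO\t./.:5:5
scf1\t90\t.\tG\tC\t70.0\t.\t.\tGT:RO:AO\t0/0:30:0
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


class TestKmerHistogram:
    def test_parse_two_columns(self, tmp_path):
        p = tmp_path / "h.histo"
        p.write_text("1 100\n2 50\n")
        hist = read_kmer_histogram(p)
        assert hist.entries == [(1, 100), (2, 50)]

    def test_non_increasing_multiplicities_rejected(self, tmp_path):
        p = tmp_path / "h.histo"
        p.write_text("2 50\n1 100\n")
        with pytest.raises(FormatError, match="increasing"):
            read_kmer_histogram(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "h.histo"
        p.write_text("")
        with pytest.raises(FormatError, match="empty"):
            read_kmer_histogram(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "h.histo"
        p.write_text("1 100\n2 fifty\n")
        with pytest.raises(FormatError, match=":2"):
            read_kmer_histogram(p)

    def test_round_trip_identity(self, tmp_path, rng):
        mult = np.cumsum(rng.integers(1, 4, size=30))
        counts = rng.integers(0, 10_000, size=30)
        counts[0] = 1  # not all zero
        hist = KmerHistogram(tuple(int(m) for m in mult), tuple(int(c) for c in counts))
        p = tmp_path / "rt.histo"
        write_kmer_histogram(hist, p)
        assert read_kmer_histogram(p) == hist

    @pytest.mark.parametrize(
        "entries",
        [
            [(1, 5)],  # too short
            [(1, 0), (2, 0)],  # all-zero counts
            [(0, 5), (1, 5)],  # non-positive multiplicity
        ],
    )
    def test_invariants_enforced(self, entries):
        with pytest.raises(ValueError):
            KmerHistogram.from_entries(entries)


class TestAlleleDepths:
    def test_quality_and_biallelic_filters(self, toy_vcf):
        records = read_allele_depths(toy_vcf)
        # of 9 records: QUAL<=20 removes 2, multiallelic 1, indel 1,
        # missing GT 1, hom-ref 1 -> 3 remain
        assert len(records) == 3
        positions = sorted(r.position for r in records)
        assert positions == [10, 40, 50]
        assert all(r.quality > 20 for r in records)

    def test_ad_fallback_depths(self, toy_vcf):
        records = read_allele_depths(toy_vcf)
        by_pos = {r.position: r for r in records}
        assert (by_pos[50].depth_ref, by_pos[50].depth_alt) == (7, 9)

    def test_genotype_classes(self, toy_vcf):
        by_pos = {r.position: r for r in read_allele_depths(toy_vcf)}
        assert by_pos[10].genotype_class == "heterozygous"
        assert by_pos[40].genotype_class == "homozygous_alt"

    def test_chrom_class_from_assignment(self, toy_vcf):
        records = read_allele_depths(toy_vcf, {"scf1": "autosome"})
        by_scaffold = {r.scaffold: r.chrom_class for r in records}
        assert by_scaffold["scf1"] == "autosome"
        assert by_scaffold["scf2"] == "unknown"

    def test_simulated_depths_recovered_exactly(self, pge_sample, pge_bundle_dir):
        records = read_allele_depths(
            pge_bundle_dir / "sample.vcf", pge_bundle_dir / "assignment.tsv"
        )
        # compare as unordered multisets: simulated positions may collide
        expect = sorted(
            (r.scaffold, r.position, r.genotype_class, r.depth_ref, r.depth_alt)
            for r in pge_sample.records
        )
        got = sorted(
            (r.scaffold, r.position, r.genotype_class, r.depth_ref, r.depth_alt)
            for r in records
        )
        assert got == expect

    def test_het_record_needs_both_depths(self):
        with pytest.raises(ValueError, match="positive depth"):
            AlleleDepthRecord("s", 1, "heterozygous", 0, 7, 30.0)


class TestSync:
    def test_parse_counts(self, tmp_path):
        p = tmp_path / "a.sync"
        p.write_text("scf1\t10\tA\t20:11:0:0:0:0\n")
        sites = read_sync(p)
        assert sites == [PileupSite("scf1", 10, (20, 11, 0, 0, 0, 0))]

    def test_bad_count_field_rejected(self, tmp_path):
        p = tmp_path / "a.sync"
        p.write_text("scf1\t10\tA\t20:11:0:0\n")
        with pytest.raises(FormatError, match="parts"):
            read_sync(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "a.sync"
        p.write_text("scf1\t10\tA\n")
        with pytest.raises(FormatError, match="columns"):
            read_sync(p)

    def test_second_sample_column(self, tmp_path):
        p = tmp_path / "a.sync"
        p.write_text("scf1\t10\tA\t1:0:0:0:0:0\t2:3:0:0:0:0\n")
        assert read_sync(p, sample=1)[0].counts == (2, 3, 0, 0, 0, 0)

    def test_round_trip(self, tmp_path, pge_sample):
        subset = pge_sample.sync_sites[:500]
        p = tmp_path / "rt.sync"
        write_sync(subset, p, pge_sample.sync_ref_bases[:500])
        assert read_sync(p) == subset


class TestAssignmentTable:
    def test_round_trip_and_unassigned_skipped(self, tmp_path):
        p = tmp_path / "assign.tsv"
        write_assignment_table(
            {"s1": "autosome", "s2": "X", "s3": "unassigned"}, p
        )
        assert read_assignment_table(p) == {"s1": "autosome", "s2": "X"}

    def test_unknown_class_rejected(self, tmp_path):
        p = tmp_path / "assign.tsv"
        p.write_text("s1\tY\n")
        with pytest.raises(FormatError, match="unknown class"):
            read_assignment_table(p)


def test_filters_are_order_independent(tmp_path):
    """Permuting VCF body lines permutes, not changes, the retained records."""
    lines = TOY_VCF.strip().split("\n")
    n_header = sum(1 for l in lines if l.startswith("#"))
    header, records = lines[:n_header], lines[n_header:]
    forward = tmp_path / "f.vcf"
    backward = tmp_path / "b.vcf"
    forward.write_text("\n".join(header + records) + "\n")
    backward.write_text("\n".join(header + records[::-1]) + "\n")
    key = lambda r: (r.scaffold, r.position)  # noqa: E731
    assert sorted(read_allele_depths(forward), key=key) == sorted(
        read_allele_depths(backward), key=key
    )
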