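import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retroscout.formats_io import (
    AnnotationSet,
    GenomicInterval,
    GffRecord,
    ParseError,
    read_bedgraph,
    read_fasta,
    read_gff3,
    read_reads,
    write_bedgraph,
    write_gff3,
)
from retroscout.synthio import rasterize_reads


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestFasta:
    def test_two_record_parse(self, tmp_path):
        p = write(tmp_path, "g.fa", ">a\nACGT\nACG\n>b desc\nTTTT\n")
        g = read_fasta(p)
        assert list(g.contigs) == ["a", "b"]
        assert g.contigs["a"] == "ACGTACG"
        assert g.lengths == {"a": 7, "b": 4}

    def test_lowercase_and_u_normalized(self, tmp_path):
        p = write(tmp_path, "g.fa", ">a\nacgu\n")
        assert read_fasta(p).contigs["a"] == "ACGT"

    def test_illegal_character_names_line(self, tmp_path):
        p = write(tmp_path, "g.fa", ">a\nACGT\nAXGT\n")
        with pytest.raises(ParseError, match="line 3"):
            read_fasta(p)

    def test_gap_characters_rejected(self, tmp_path):
        p = write(tmp_path, "g.fa", ">a\nAC-GT\n")
        with pytest.raises(ParseError):
            read_fasta(p)

    def test_fetch_minus_strand_reverse_complements(self, tmp_path):
        p = write(tmp_path, "g.fa", ">a\nAACGTT\n")
        g = read_fasta(p)
        assert g.fetch(GenomicInterval("a", 0, 4, "-")) == "CGTT"


class TestGff3:
    def test_coordinate_convention(self, tmp_path):
        p = write(tmp_path, "a.gff3",
                  "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n")
        ann = read_gff3(p)
        assert ann.records[0].interval == GenomicInterval("chr1", 100, 200, "+")

    def test_round_trip_byte_stable(self, tmp_path):
        lines = ["##gff-version 3"]
        for i in range(10):
            lines.append(
                f"chr1\tsrc\tgene\t{i * 50 + 1}\t{i * 50 + 40}\t0.{i}\t"
                f"{'+' if i % 2 else '-'}\t.\tID=g{i};Note=x{i}"
            )
        p = write(tmp_path, "a.gff3", "\n".join(lines) + "\n")
        out = tmp_path / "b.gff3"
        write_gff3(read_gff3(p), out)
        assert out.read_text() == p.read_text()

    def test_end_before_start_rejected(self, tmp_path):
        p = write(tmp_path, "a.gff3", "chr1\ts\tg\t200\t100\t.\t+\t.\tID=x\n")
        with pytest.raises(ParseError):
            read_gff3(p)

    def test_overlap_query_matches_linear_scan(self):
        rng = np.random.default_rng(0)
        ann = AnnotationSet()
        for i in range(500):
            s = int(rng.integers(0, 10_000))
            e = s + int(rng.integers(1, 300))
            ann.add(GffRecord(GenomicInterval("c", s, e), "gene",
                              attributes=f"ID=r{i}"))
        for _ in range(50):
            q0 = int(rng.integers(0, 10_000))
            q = GenomicInterval("c", q0, q0 + 120)
            fast = {r.attributes for r in ann.overlapping(q)}
            slow = {r.attributes for r in ann.records if r.interval.overlaps(q)}
            assert fast == slow

    def test_point_overlap_query(self, tmp_path):
        p = write(tmp_path, "a.gff3", "chr1\ts\tg\t101\t200\t.\t+\t.\tID=x\n")
        ann = read_gff3(p)
        assert len(ann.overlapping(GenomicInterval("chr1", 150, 151))) == 1
        assert len(ann.overlapping(GenomicInterval("chr1", 300, 301))) == 0


class TestBedgraph:
    LENS = {"c": 200}

    def test_full_bin_coverage(self, tmp_path):
        p = write(tmp_path, "a.bg", "c\t0\t100\t4.0\n")
        tr = read_bedgraph(p, 50, self.LENS)
        assert tr.values["c"][:2].tolist() == [4.0, 4.0]

    def test_empty_file_all_zero(self, tmp_path):
        p = write(tmp_path, "a.bg", "")
        assert not read_bedgraph(p, 50, self.LENS).values["c"].any()

    def test_partial_bin_length_weighted_mean(self, tmp_path):
        # [0,75) at 4.0 with 50 bp bins: second bin is (4*25 + 0*25)/50 = 2
        p = write(tmp_path, "a.bg", "c\t0\t75\t4.0\n")
        tr = read_bedgraph(p, 50, self.LENS)
        assert tr.values["c"][:2].tolist() == [4.0, 2.0]

    def test_overlapping_intervals_rejected(self, tmp_path):
        p = write(tmp_path, "a.bg", "c\t0\t100\t4.0\nc\t50\t150\t2.0\n")
        with pytest.raises(ParseError, match="ambiguous"):
            read_bedgraph(p, 50, self.LENS)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.tuples(st.integers(0, 30), st.integers(1, 20),
                              st.floats(0.1, 50)), max_size=6))
    def test_write_read_rasterization_fixpoint(self, tmp_path_factory, spans):
        """rasterize(write(read(x))) == rasterize(read(x))."""
        tmp = tmp_path_factory.mktemp("bg")
        # build non-overlapping intervals from offsets
        pos, lines = 0, []
        for gap, length, value in spans:
            start = pos + gap
            end = start + length
            if end > 400:
                break
            lines.append(f"c\t{start}\t{end}\t{value:.3f}")
            pos = end
        p = write(tmp, "a.bg", "\n".join(lines) + ("\n" if lines else ""))
        tr1 = read_bedgraph(p, 25, {"c": 400})
        out = tmp / "b.bg"
        write_bedgraph(tr1, out)
        tr2 = read_bedgraph(out, 25, {"c": 400})
        np.testing.assert_allclose(tr2.values["c"], tr1.values["c"], atol=1e-9)


class TestReads:
    def test_tsv_row(self, tmp_path, small_dataset):
        _, genome, _ = small_dataset
        contig = next(iter(genome.contigs))
        p = write(tmp_path, "r.tsv", f"{contig}\t100\t124\t+\t3\n")
        (r,) = read_reads(p, genome)
        assert (r.length, r.count, r.strand) == (24, 3, "+")
        base = genome.contigs[contig][100]
        assert r.five_prime_nt == ("U" if base == "T" else base)

    def test_minus_strand_five_prime_from_end(self, tmp_path):
        g_path = write(tmp_path, "g.fa", ">c\n" + "A" * 30 + "G" + "A" * 30 + "\n")
        genome = read_fasta(g_path)
        p = write(tmp_path, "r.tsv", "c\t7\t31\t-\t1\n")
        (r,) = read_reads(p, genome)
        # 5' end of a minus read is the complement of the base at end-1
        assert r.five_prime_nt == "C"

    def test_bad_strand_and_coords_rejected(self, tmp_path):
        p1 = write(tmp_path, "r1.tsv", "c\t5\t30\t?\t1\n")
        with pytest.raises(ParseError, match="strand"):
            read_reads(p1)
        p2 = write(tmp_path, "r2.tsv", "c\t30\t5\t+\t1\n")
        with pytest.raises(ParseError):
            read_reads(p2)

    def test_sam_input_coordinates(self, tmp_path):
        g_path = write(tmp_path, "g.fa", ">chr1\n" + "ACGT" * 100 + "\n")
        genome = read_fasta(g_path)
        sam = ("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:400\n"
               "r1\t0\tchr1\t101\t60\t24M\t*\t0\t0\t*\t*\n"
               "r2\t16\tchr1\t11\t60\t20M\t*\t0\t0\t*\t*\n")
        p = write(tmp_path, "r.sam", sam)
        reads = read_reads(p, genome)
        assert reads[0].interval == GenomicInterval("chr1", 100, 124, "+")
        assert reads[1].strand == "-" and reads[1].length == 20

    def test_rasterized_mass_is_conserved(self, tmp_path, small_dataset):
        _, genome, _ = small_dataset
        contig = next(iter(genome.contigs))
        rows = "".join(f"{contig}\t{i * 40}\t{i * 40 + 24}\t+\t2\n"
                       for i in range(10))
        reads = read_reads(write(tmp_path, "r.tsv", rows), genome)
        track = rasterize_reads(reads, genome.lengths, 50)
        track_raw = rasterize_reads(reads, genome.lengths, 50)
        # RPKM scaling aside, per-read mass sums to the read count
        total = sum(v.sum() for v in track_raw.values.values())
        scale = 1.0 / ((50 / 1000) * (20 / 1e6))
        assert total == pytest.approx(20 * scale)


class TestGenomicInterval:
    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("c", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("c", 5, 3)
        with pytest.raises(ValueError):
            GenomicInterval("c", 0, 5, "x")

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 50), st.integers(1, 30), st.integers(0, 50),
           st.integers(1, 30))
    def test_overlap_len_consistent_with_overlaps(self, s1, l1, s2, l2):
        a = GenomicInterval("c", s1, s1 + l1)
        b = GenomicInterval("c", s2, s2 + l2)
        assert (a.overlap_len(b) > 0) == a.overlaps(b)
        assert a.overlap_len(b) == b.overlap_len(a)
        if not a.overlaps(b):
            assert a.distance(b) == max(a.start, b.start) - min(a.end, b.end)
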