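import numpy as np
import pandas as pd
import pytest

import ctccnv as cc
from ctccnv.genome import (
    ChromInfo,
    GenomeError,
    Segment,
    SegmentSet,
    matrix_for_grid,
    read_seg,
)
from ctccnv.simulate import HG38_CHROM_SIZES


class TestChromSizes:
    def test_parses_names_and_lengths(self, tmp_path):
        p = tmp_path / "chrom.sizes"
        p.write_text("chr1\t248956422\nchr2\t242193529\n")
        chroms = cc.read_chrom_sizes(p)
        assert [(c.name, c.length) for c in chroms] == [
            ("chr1", 248956422), ("chr2", 242193529)]

    @pytest.mark.parametrize("content,msg", [
        ("chr1\t100\nchr1\t200\n", "duplicate"),
        ("chr1\tabc\n", "non-integer"),
        ("", "empty"),
    ])
    def test_rejects_malformed_input(self, tmp_path, content, msg):
        p = tmp_path / "bad.sizes"
        p.write_text(content)
        with pytest.raises(GenomeError, match=msg):
            cc.read_chrom_sizes(p)


class TestBinGrid:
    def test_trailing_partial_bin_kept_and_flagged(self):
        grid = cc.make_bin_grid([ChromInfo("c", 3_500_000)], 1_000_000)
        assert grid.n_bins == 4
        assert grid.widths.tolist() == [1_000_000] * 3 + [500_000]
        assert grid.partial.tolist() == [False, False, False, True]

    def test_chromosome_shorter_than_bin(self):
        grid = cc.make_bin_grid([ChromInfo("c", 400_000)], 1_000_000)
        assert grid.n_bins == 1 and grid.partial[0]

    def test_tiling_covers_genome_exactly_once(self, small_genome):
        grid = cc.make_bin_grid(small_genome, 1_000_000)
        assert grid.widths.sum() == sum(c.length for c in small_genome)
        for sl in grid.chrom_slices().values():
            starts, ends = grid.start[sl], grid.end[sl]
            assert starts[0] == 0
            assert (starts[1:] == ends[:-1]).all()

    def test_hg38_scale_bin_count(self):
        genome = [ChromInfo(n, l) for n, l in HG38_CHROM_SIZES]
        grid = cc.make_bin_grid(genome, 1_000_000)
        expected = sum(-(-l // 1_000_000) for _, l in HG38_CHROM_SIZES)
        assert grid.n_bins == expected
        assert 3000 <= grid.n_bins <= 3200


class TestGCAnnotation:
    def test_gc_from_sequence_conventions(self, tmp_path):
        import pysam

        fasta = tmp_path / "toy.fa"
        seq_g = "G" * 1000
        seq_acgt = "ACGT" * 250
        seq_n = "N" * 1000
        fasta.write_text(f">c1\n{seq_g}{seq_acgt}{seq_n}\n")
        pysam.faidx(str(fasta))
        grid = cc.make_bin_grid([ChromInfo("c1", 3000)], 1000)
        grid = cc.annotate_gc(grid, fasta)
        assert grid.gc[0] == 1.0
        assert grid.gc[1] == 0.5
        assert np.isnan(grid.gc[2])


class TestReadCounting:
    def test_mapq_duplicate_and_assignment_rules(self, tiny_sam, small_grid):
        counts = cc.count_reads_in_intervals(tiny_sam, small_grid)
        # bin chr1:1-2 Mb: 10 good reads; 4 duplicates dropped
        assert counts[1] == 10
        # bin chr1:0-1 Mb: only MAPQ-29 reads, all filtered
        assert counts[0] == 0
        # leftmost-base assignment puts the boundary read in bin 2
        assert counts[2] == 1
        chr2_offset = 60  # chr1 occupies 60 bins
        assert counts[chr2_offset + 5] == 1
        assert counts.sum() == 12

    def test_mapq_threshold_is_strict(self, tiny_sam, small_grid):
        relaxed = cc.count_reads_in_intervals(tiny_sam, small_grid, min_mapq=29)
        assert relaxed[0] == 3

    def test_keeping_duplicates(self, tiny_sam, small_grid):
        counts = cc.count_reads_in_intervals(tiny_sam, small_grid, drop_duplicates=False)
        assert counts[1] == 14

    def test_warns_on_missing_chromosome(self, tiny_sam):
        grid = cc.make_bin_grid([ChromInfo("chrZ", 1_000_000)], 1_000_000)
        with pytest.warns(UserWarning, match="chrZ"):
            counts = cc.count_reads_in_intervals(tiny_sam, grid)
        assert counts.sum() == 0


class TestCountMatrixIO:
    def test_round_trip_identity(self, small_grid, tmp_path, rng):
        counts = {f"cell{i}": rng.integers(0, 100, small_grid.n_bins) for i in range(3)}
        mat = matrix_for_grid(small_grid, counts)
        p = tmp_path / "m.tsv"
        cc.write_count_matrix(mat, p)
        back = cc.read_count_matrix(p)
        assert back.shape == mat.shape
        np.testing.assert_array_equal(back.values, mat.values)
        assert list(back.columns) == list(mat.columns)

    def test_negative_counts_rejected(self, small_grid, tmp_path):
        mat = matrix_for_grid(small_grid, {"c": np.zeros(small_grid.n_bins, int)})
        mat.iloc[0, 0] = -1
        with pytest.raises(GenomeError, match="negative"):
            cc.write_count_matrix(mat, tmp_path / "m.tsv")

    def test_missing_cell_columns_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chrom\tstart\tend\nchr1\t0\t100\n")
        with pytest.raises(GenomeError, match="cell"):
            cc.read_count_matrix(p)


class TestSegIO:
    def test_seg_line_format_is_one_based_inclusive(self, tmp_path):
        ss = SegmentSet("cell1", [Segment("cell1", "chr1", 0, 10_000_000, 10, 0.0)])
        p = tmp_path / "out.seg"
        cc.write_seg(ss, p)
        lines = p.read_text().strip().split("\n")
        assert lines[0].split("\t") == ["ID", "chrom", "loc.start", "loc.end",
                                        "num.mark", "seg.mean"]
        assert lines[1].split("\t") == ["cell1", "chr1", "1", "10000000", "10", "0.0000"]

    def test_empty_set_writes_header_only(self, tmp_path):
        p = tmp_path / "empty.seg"
        cc.write_seg(SegmentSet("c", []), p)
        assert p.read_text().strip().split("\n") == [
            "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean"]

    def test_round_trip(self, tmp_path):
        ss = SegmentSet("c", [
            Segment("c", "chr1", 0, 10_000_000, 10, 0.5),
            Segment("c", "chr1", 10_000_000, 25_000_000, 15, -1.25),
            Segment("c", "chr2", 0, 5_000_000, 5, 0.0),
        ])
        p = tmp_path / "rt.seg"
        cc.write_seg(ss, p)
        back = read_seg(p)
        assert len(back) == 1
        for orig, rt in zip(ss.segments, back[0].segments):
            assert (orig.chrom, orig.start_bp, orig.end_bp, orig.n_bins) == \
                   (rt.chrom, rt.start_bp, rt.end_bp, rt.n_bins)
            assert rt.mean_log2 == pytest.approx(orig.mean_log2, abs=5e-5)


class TestGeneTableIO:
    def test_bed_and_tabular_inputs_agree(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("chr1\t1000\t51000\tPTEN\t0\t+\nchrX\t500\t2500\tAR\t0\t+\n")
        tab = tmp_path / "g.tsv"
        tab.write_text("name\tchrom\ttxStart\ttxEnd\nPTEN\tchr1\t1000\t51000\nAR\tchrX\t500\t2500\n")
        g1 = cc.read_genes(bed)
        g2 = cc.read_genes(tab)
        assert [(g.name, g.chrom, g.tx_start, g.tx_end) for g in g1] == \
               [(g.name, g.chrom, g.tx_start, g.tx_end) for g in g2]
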