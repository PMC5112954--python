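import numpy as np
import pytest

import ctccnv as cc
from ctccnv.genome import ChromInfo


@pytest.fixture(scope="session")
def small_genome():
    return [ChromInfo("chr1", 60_000_000), ChromInfo("chr2", 40_000_000)]


@pytest.fixture(scope="session")
def small_grid(small_genome):
    grid = cc.make_bin_grid(small_genome, 1_000_000)
    grid.gc = cc.make_bin_gc(grid, seed=3)
    return grid


@pytest.fixture(scope="session")
def toy_cohort():
    """A small simulated cohort shared across tests (cheap: 200 bins/cell)."""
    genome = [ChromInfo("chr1", 120_000_000), ChromInfo("chr2", 80_000_000)]
    cfg = cc.SimConfig(seed=7, genome=genome, total_reads=600_000, n_wbc=5, n_tumor=3)
    return cc.simulate_cohort(cfg, group_events={"tumorA": 3}, min_flank_bp=12_000_000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_sam(tmp_path_factory):
    """A coordinate-sorted SAM with known MAPQ/duplicate structure on chr1."""
    import pysam

    path = tmp_path_factory.mktemp("aln") / "tiny.sam"
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "chr1", "LN": 60_000_000},
                     {"SN": "chr2", "LN": 40_000_000}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        def read(name, chrom, pos, mapq, dup=False):
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.query_sequence = "A" * 50
            a.query_qualities = pysam.qualitystring_to_array("I" * 50)
            a.reference_id = 0 if chrom == "chr1" else 1
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = "50M"
            a.flag = 1024 if dup else 0
            return a

        rows = []
        # 10 good reads in bin 1 (1,000,000-2,000,000)
        rows += [read(f"good{i}", "chr1", 1_000_000 + i * 1000, 60) for i in range(10)]
        # 4 duplicates in the same bin
        rows += [read(f"dup{i}", "chr1", 1_200_000 + i * 500, 60, dup=True) for i in range(4)]
        # low-MAPQ reads in bin 0
        rows += [read(f"lowq{i}", "chr1", 10_000 + i * 100, 29) for i in range(3)]
        # boundary read: leftmost base in bin 2 exactly at its start
        rows += [read("edge", "chr1", 2_000_000, 60)]
        # one read on chr2
        rows += [read("c2", "chr2", 5_000_000, 60)]
        for a in sorted(rows, key=lambda a: (a.reference_id, a.reference_start)):
            out.write(a)
    return path
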