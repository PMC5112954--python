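"""Genomic coordinate system (chromosomes, fixed-width bins, gene loci) and file IO.

All coordinates are 0-based half-open internally.  SEG output follows the
UCSC/DNAcopy convention (1-based inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class GenomeError(ValueError):
    """Raised for malformed genome/interval inputs."""


@dataclass(frozen=True)
class ChromInfo:
    """A chromosome and its length in base pairs."""

    name: str
    length: int

    def __post_init__(self):
        if self.length <= 0:
            raise GenomeError(f"chromosome {self.name!r} has non-positive length {self.length}")


@dataclass
class BinGrid:
    """Ordered fixed-width genomic windows tiling a genome.

    ``gc`` is the per-bin GC fraction in [0, 1]; NaN marks bins without a GC
    estimate (e.g. all-N sequence), which are passed through GC fitting
    unadjusted.  The trailing bin of each chromosome may be shorter than
    ``bin_width`` and is flagged in ``partial``.
    """

    chrom: np.ndarray          # str per bin
    start: np.ndarray          # int64
    end: np.ndarray            # int64
    bin_width: int
    gc: np.ndarray             # float64, NaN = missing
    partial: np.ndarray        # bool
    chromosomes: list[ChromInfo] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def widths(self) -> np.ndarray:
        return self.end - self.start

    def bin_ids(self) -> list[str]:
        return [f"{c}:{s}-{e}" for c, s, e in zip(self.chrom, self.start, self.end)]

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous index slice per chromosome, in grid order."""
        out: dict[str, slice] = {}
        i = 0
        while i < self.n_bins:
            c = self.chrom[i]
            j = i
            while j < self.n_bins and self.chrom[j] == c:
                j += 1
            out[c] = slice(i, j)
            i = j
        return out

    def autosome_mask(self) -> np.ndarray:
        sex = {"chrX", "chrY", "X", "Y"}
        return ~np.isin(self.chrom, list(sex))


@dataclass(frozen=True)
class GeneLocus:
    """A gene's transcript span plus the (possibly extended) counting span."""

    name: str
    chrom: str
    tx_start: int
    tx_end: int
    ext_start: int = -1
    ext_end: int = -1

    def __post_init__(self):
        if not self.tx_start < self.tx_end:
            raise GenomeError(f"gene {self.name!r}: tx_start must be < tx_end")
        if self.ext_start < 0:
            object.__setattr__(self, "ext_start", self.tx_start)
        if self.ext_end < 0:
            object.__setattr__(self, "ext_end", self.tx_end)

    @property
    def ext_span(self) -> int:
        return self.ext_end - self.ext_start


@dataclass
class CellMeta:
    cell_id: str
    group_id: str = ""
    cell_class: str = ""      # CTC | WBC | cell-line
    total_reads: int = 0
    qc_flags: tuple[str, ...] = ()


@dataclass
class Segment:
    cell_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_bins: int
    mean_log2: float

    @property
    def span(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class SegmentSet:
    cell_id: str
    segments: list[Segment]
    params: dict = field(default_factory=dict)

    def by_chrom(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for s in self.segments:
            out.setdefault(s.chrom, []).append(s)
        for segs in out.values():
            segs.sort(key=lambda s: s.start_bp)
        return out


# ---------------------------------------------------------------------------
# readers / writers


def read_chrom_sizes(path) -> list[ChromInfo]:
    """Parse a two-column chrom.sizes TSV (name, length)."""
    chroms: list[ChromInfo] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GenomeError(f"{path}:{lineno}: expected two tab-separated columns")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError:
                raise GenomeError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from None
            if name in seen:
                raise GenomeError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            chroms.append(ChromInfo(name, length))
    if not chroms:
        raise GenomeError(f"{path}: empty genome (no chromosomes)")
    return chroms


def make_bin_grid(genome: list[ChromInfo], bin_width: int = 1_000_000) -> BinGrid:
    """Tile each chromosome with contiguous bins of ``bin_width`` bp.

    The trailing bin of a chromosome is kept even when shorter than
    ``bin_width`` and flagged as partial.
    """
    if bin_width <= 0:
        raise GenomeError("bin_width must be positive")
    chrom, start, end, partial = [], [], [], []
    for c in genome:
        edges = list(range(0, c.length, bin_width)) + [c.length]
        for s, e in zip(edges[:-1], edges[1:]):
            chrom.append(c.name)
            start.append(s)
            end.append(e)
            partial.append(e - s != bin_width)
    return BinGrid(
        chrom=np.array(chrom, dtype=object),
        start=np.array(start, dtype=np.int64),
        end=np.array(end, dtype=np.int64),
        bin_width=bin_width,
        gc=np.full(len(start), np.nan),
        partial=np.array(partial, dtype=bool),
        chromosomes=list(genome),
    )


def annotate_gc(grid: BinGrid, sequence_source) -> BinGrid:
    """Fill per-bin GC fractions.

    ``sequence_source`` is either a FASTA path (read with pysam) or a
    mapping/callable giving the sequence for a chromosome.  Bins consisting
    only of N bases get NaN GC and are excluded from GC fitting downstream.
    """
    import pysam

    if isinstance(sequence_source, (str, bytes)) or hasattr(sequence_source, "__fspath__"):
        fasta = pysam.FastaFile(str(sequence_source))
        fetch = lambda c, s, e: fasta.fetch(c, s, e)  # noqa: E731
    elif isinstance(sequence_source, dict):
        fetch = lambda c, s, e: sequence_source[c][s:e]  # noqa: E731
    else:
        fetch = sequence_source

    gc = np.full(grid.n_bins, np.nan)
    for i in range(grid.n_bins):
        seq = fetch(grid.chrom[i], int(grid.start[i]), int(grid.end[i])).upper()
        if len(seq) != grid.end[i] - grid.start[i]:
            raise GenomeError(
                f"interval {grid.chrom[i]}:{grid.start[i]}-{grid.end[i]} outside sequence"
            )
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt == 0:
            continue
        gc[i] = (seq.count("G") + seq.count("C")) / acgt
    out = replace(grid)
    out.gc = gc
    return out


def count_reads_in_intervals(
    alignments,
    intervals,
    min_mapq: int = 30,
    drop_duplicates: bool = True,
    assign: str = "leftmost",
) -> np.ndarray:
    """Count filtered reads into intervals (a BinGrid or list of GeneLocus).

    Reads with MAPQ below ``min_mapq``, duplicate-flagged, unmapped or
    secondary/supplementary alignments are excluded.  A read is assigned to
    the interval containing its leftmost aligned base (or its midpoint when
    ``assign='midpoint'``).  The file is streamed start to end, so a plain
    SAM file works; intervals on chromosomes absent from the header count 0
    with a warning.
    """
    import pysam

    if isinstance(intervals, BinGrid):
        iv_chrom, iv_start, iv_end = intervals.chrom, intervals.start, intervals.end
    else:
        iv_chrom = np.array([g.chrom for g in intervals], dtype=object)
        iv_start = np.array([g.ext_start for g in intervals], dtype=np.int64)
        iv_end = np.array([g.ext_end for g in intervals], dtype=np.int64)

    # per-chromosome sorted interval edges for searchsorted assignment
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for c in np.unique(iv_chrom.astype(str)):
        idx = np.where(iv_chrom == c)[0]
        order = np.argsort(iv_start[idx], kind="stable")
        idx = idx[order]
        by_chrom[c] = (iv_start[idx], iv_end[idx], idx)

    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        af = pysam.AlignmentFile(str(alignments), check_sq=False)
    else:
        af = alignments

    header_chroms = set(af.references or ())
    missing = set(by_chrom) - header_chroms
    if missing:
        warnings.warn(f"intervals on chromosomes absent from alignment header: {sorted(missing)}")

    counts = np.zeros(len(iv_chrom), dtype=np.int64)
    for read in af:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.mapping_quality < min_mapq:
            continue
        if drop_duplicates and read.is_duplicate:
            continue
        c = read.reference_name
        entry = by_chrom.get(c)
        if entry is None:
            continue
        starts, ends, idx = entry
        if assign == "midpoint":
            pos = (read.reference_start + read.reference_end) // 2 if read.reference_end else read.reference_start
        else:
            pos = read.reference_start
        k = np.searchsorted(starts, pos, side="right") - 1
        if k >= 0 and pos < ends[k]:
            counts[idx[k]] += 1
    return counts


def read_count_matrix(path) -> pd.DataFrame:
    """Read a count-matrix TSV: identifier columns then one column per cell.

    Bin matrices carry (chrom, start, end) identifier columns; gene matrices
    carry a single ``gene`` column.  Returns a DataFrame indexed by the
    identifier(s) with integer cell columns.
    """
    df = pd.read_csv(path, sep="\t")
    if {"chrom", "start", "end"}.issubset(df.columns):
        id_cols = ["chrom", "start", "end"]
    elif "gene" in df.columns:
        id_cols = ["gene"]
    else:
        raise GenomeError(f"{path}: missing identifier columns (chrom/start/end or gene)")
    cells = [c for c in df.columns if c not in id_cols]
    if not cells:
        raise GenomeError(f"{path}: no cell columns")
    mat = df.set_index(id_cols)[cells]
    if (mat.values < 0).any():
        raise GenomeError(f"{path}: negative counts")
    return mat


def write_count_matrix(matrix: pd.DataFrame, path) -> None:
    if (matrix.values < 0).any():
        raise GenomeError("negative counts")
    matrix.reset_index().to_csv(path, sep="\t", index=False)


def matrix_for_grid(grid: BinGrid, counts: dict[str, np.ndarray]) -> pd.DataFrame:
    """Assemble per-cell count vectors into a bin-indexed matrix."""
    idx = pd.MultiIndex.from_arrays(
        [grid.chrom.astype(str), grid.start, grid.end], names=["chrom", "start", "end"]
    )
    for cid, v in counts.items():
        if len(v) != grid.n_bins:
            raise GenomeError(f"cell {cid}: {len(v)} values for {grid.n_bins} bins")
    return pd.DataFrame(counts, index=idx)


SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def write_seg(segments: SegmentSet | list[SegmentSet], path) -> None:
    """Write SEG-format TSV (1-based inclusive output coordinates)."""
    sets = segments if isinstance(segments, list) else [segments]
    rows = []
    for ss in sets:
        for s in ss.segments:
            rows.append(
                (ss.cell_id, s.chrom, s.start_bp + 1, s.end_bp, s.n_bins, f"{s.mean_log2:.4f}")
            )
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_seg(path) -> list[SegmentSet]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for cid, sub in df.groupby("ID", sort=False):
        segs = [
            Segment(cid, r["chrom"], int(r["loc.start"]) - 1, int(r["loc.end"]),
                    int(r["num.mark"]), float(r["seg.mean"]))
            for _, r in sub.iterrows()
        ]
        out.append(SegmentSet(cell_id=cid, segments=segs))
    return out


def read_genes(path) -> list[GeneLocus]:
    """Read gene loci from BED (>=4 columns) or refFlat-style TSV.

    Only name, chrom, txStart and txEnd are used.
    """
    with open(path) as fh:
        first = fh.readline()
    cols = first.rstrip("\n").split("\t")
    genes: list[GeneLocus] = []
    if len(cols) >= 4 and cols[1].isdigit() and cols[2].isdigit():
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
        for _, r in bed.iterrows():
            genes.append(GeneLocus(name=str(r[3]), chrom=str(r[0]), tx_start=int(r[1]), tx_end=int(r[2])))
    else:
        df = pd.read_csv(path, sep="\t")
        lower = {c.lower(): c for c in df.columns}
        name_c = lower.get("name") or lower.get("gene") or lower.get("genename")
        chrom_c = lower.get("chrom")
        s_c = lower.get("txstart") or lower.get("tx_start") or lower.get("start")
        e_c = lower.get("txend") or lower.get("tx_end") or lower.get("end")
        if not all([name_c, chrom_c, s_c, e_c]):
            raise GenomeError(f"{path}: unrecognized gene table columns {list(df.columns)}")
        for _, r in df.iterrows():
            genes.append(GeneLocus(name=str(r[name_c]), chrom=str(r[chrom_c]),
                                   tx_start=int(r[s_c]), tx_end=int(r[e_c])))
    return genes
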