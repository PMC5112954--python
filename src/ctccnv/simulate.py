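"""Synthetic single-cell WGA-like count generator with ground truth.

Emulates ~0.01x-coverage single-cell whole-genome-amplified sequencing:
per-bin expected coverage proportional to copy number, modulated by a smooth
GC-bias curve, per-bin gamma-distributed amplification noise (giving
negative-binomial counts), and occasional multiplicative dropout.  Reads are
allocated by a multinomial draw so each cell has an exact total.  Tumor-like
truths are alternating diploid / non-diploid segmental CNVs whose
breakpoints all qualify as large-scale state transitions by construction
(both flanks >= the flank floor, adjacent copy numbers differ by >= 0.8 in
log2), so the intended breakpoint count is the truth LST.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import BinGrid, ChromInfo, GeneLocus, make_bin_grid

# Desk-scale toy genome used throughout the test-suite simulations.  Sized so
# that the highest tested instability level (~30 breakpoints with >= 12 Mb
# flanks) leaves typical segments well above the 10 Mb LST flank floor, as
# they are on a full-size genome.
TOY_CHROM_SIZES = [
    ("chr1", 250_000_000),
    ("chr2", 230_000_000),
    ("chr3", 210_000_000),
    ("chr4", 190_000_000),
    ("chr5", 170_000_000),
    ("chr6", 150_000_000),
]

# hg38 chromosome lengths (UCSC), for full-scale simulations such as the
# read-depth titration, where the per-bin depth regime matters.
HG38_CHROM_SIZES = [
    ("chr1", 248_956_422), ("chr2", 242_193_529), ("chr3", 198_295_559),
    ("chr4", 190_214_555), ("chr5", 181_538_259), ("chr6", 170_805_979),
    ("chr7", 159_345_973), ("chr8", 145_138_636), ("chr9", 138_394_717),
    ("chr10", 133_797_422), ("chr11", 135_086_622), ("chr12", 133_275_309),
    ("chr13", 114_364_328), ("chr14", 107_043_718), ("chr15", 101_991_189),
    ("chr16", 90_338_345), ("chr17", 83_257_441), ("chr18", 80_373_285),
    ("chr19", 58_617_616), ("chr20", 64_444_167), ("chr21", 46_709_983),
    ("chr22", 50_818_468), ("chrX", 156_040_895), ("chrY", 57_227_415),
]


def toy_genome() -> list[ChromInfo]:
    return [ChromInfo(n, l) for n, l in TOY_CHROM_SIZES]


def hg38_genome() -> list[ChromInfo]:
    return [ChromInfo(n, l) for n, l in HG38_CHROM_SIZES]


@dataclass
class SimConfig:
    genome: list[ChromInfo] = field(default_factory=toy_genome)
    bin_width: int = 1_000_000
    total_reads: int = 3_000_000
    gc_bias: tuple[float, float] = (1.5, -3.0)   # log-linear + quadratic in (gc - 0.45)
    dispersion: float = 0.05                      # NB: var = mu + dispersion * mu^2
    dropout_rate: float = 0.005
    dropout_factor: float = 0.3
    n_wbc: int = 15
    n_tumor: int = 8
    seed: int = 1

    def __post_init__(self):
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class TruthProfile:
    """Ground-truth segmental copy state: per-chromosome (start, end, copy)."""

    segments: dict[str, list[tuple[int, int, int]]]
    ploidy: int = 2

    def copy_per_bin(self, grid: BinGrid) -> np.ndarray:
        copy = np.full(grid.n_bins, float(self.ploidy))
        for i in range(grid.n_bins):
            segs = self.segments.get(str(grid.chrom[i]))
            if not segs:
                continue
            mid = (grid.start[i] + grid.end[i]) // 2
            for s, e, c in segs:
                if s <= mid < e:
                    copy[i] = c
                    break
        return copy

    def copy_at(self, chrom: str, pos: int) -> int:
        for s, e, c in self.segments.get(chrom, []):
            if s <= pos < e:
                return c
        return self.ploidy

    def truth_lst(self, min_flank_bp: int = 10_000_000) -> int:
        """Breakpoints with differing copy number and both flanks >= min_flank_bp."""
        lst = 0
        for segs in self.segments.values():
            for (s1, e1, c1), (s2, e2, c2) in zip(segs[:-1], segs[1:]):
                if c1 != c2 and (e1 - s1) >= min_flank_bp and (e2 - s2) >= min_flank_bp:
                    lst += 1
        return lst


def simulate_truth(
    genome: list[ChromInfo],
    n_events: int,
    min_flank_bp: int = 12_000_000,
    seed: int | np.random.Generator = 1,
    ploidy: int = 2,
    tumor_copies: tuple[int, ...] = (1, 4),
    span_max_bp: int | None = None,
) -> TruthProfile:
    """Plant ``n_events`` LST-eligible breakpoints across the genome.

    Each chromosome receiving b breakpoints is carved into b+1 alternating
    diploid / non-diploid segments, every segment spanning at least
    ``min_flank_bp`` (interior segments at most ``span_max_bp`` when given),
    so the truth LST equals ``n_events`` by construction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    capacity = {c.name: max(c.length // min_flank_bp - 1, 0) for c in genome}
    if sum(capacity.values()) < n_events:
        raise ValueError(
            f"genome cannot host {n_events} breakpoints with {min_flank_bp} bp flanks"
        )
    alloc = {c.name: 0 for c in genome}
    names = [c.name for c in genome]
    for _ in range(n_events):
        open_ = [n for n in names if alloc[n] < capacity[n]]
        weights = np.array([capacity[n] - alloc[n] for n in open_], dtype=float)
        pick = rng.choice(len(open_), p=weights / weights.sum())
        alloc[open_[pick]] += 1

    segments: dict[str, list[tuple[int, int, int]]] = {}
    for c in genome:
        b = alloc[c.name]
        if b == 0:
            segments[c.name] = [(0, c.length, ploidy)]
            continue
        if span_max_bp is not None and b >= 2:
            spans = rng.uniform(min_flank_bp, span_max_bp, size=b - 1)
            total = spans.sum()
            lo, hi = min_flank_bp, c.length - total - min_flank_bp
            if hi < lo:
                raise ValueError(f"{c.name}: clustered spans do not fit")
            first = rng.uniform(lo, hi)
            cuts = np.concatenate([[first], first + np.cumsum(spans)])
        else:
            free = c.length - (b + 1) * min_flank_bp
            if free < 0:
                raise ValueError(f"{c.name}: breakpoints do not fit")
            u = np.sort(rng.uniform(0, free, size=b))
            cuts = u + min_flank_bp * (1 + np.arange(b))
        cuts = np.round(cuts / 1_000_000).astype(np.int64) * 1_000_000
        edges = [0, *cuts.tolist(), c.length]
        segs = []
        for r, (s, e) in enumerate(zip(edges[:-1], edges[1:])):
            copy = ploidy if r % 2 == 0 else int(rng.choice(tumor_copies))
            segs.append((int(s), int(e), copy))
        segments[c.name] = segs
    return TruthProfile(segments=segments, ploidy=ploidy)


def flat_truth(genome: list[ChromInfo], ploidy: int = 2) -> TruthProfile:
    return TruthProfile({c.name: [(0, c.length, ploidy)] for c in genome}, ploidy=ploidy)


def make_bin_gc(grid: BinGrid, seed: int = 7) -> np.ndarray:
    """Synthetic per-bin GC fractions (unimodal around 0.45, as in mammalian 1-Mb bins)."""
    rng = np.random.default_rng(seed)
    return np.clip(rng.normal(0.45, 0.06, size=grid.n_bins), 0.30, 0.62)


def _gc_bias_curve(gc: np.ndarray, coefs: tuple[float, float]) -> np.ndarray:
    d = np.where(np.isfinite(gc), gc - 0.45, 0.0)
    return np.exp(coefs[0] * d + coefs[1] * d * d)


def _noisy_lambda(base: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lam = base.astype(float).copy()
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam *= rng.gamma(shape, 1.0 / shape, size=lam.size)
    if config.dropout_rate > 0:
        drop = rng.random(lam.size) < config.dropout_rate
        lam[drop] *= config.dropout_factor
    return lam


def simulate_cell_counts(
    truth: TruthProfile,
    grid: BinGrid,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    cell_id: str = "cell",
    total_reads: int | None = None,
):
    """Draw one cell's raw binned counts from the WGA noise model."""
    from .normalize import CellCountProfile

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    copy = truth.copy_per_bin(grid)
    base = copy * (grid.widths / grid.bin_width) * _gc_bias_curve(grid.gc, config.gc_bias)
    lam = _noisy_lambda(base, config, rng)
    if lam.sum() <= 0:
        raise ValueError("degenerate simulation: zero total intensity")
    n = total_reads if total_reads is not None else config.total_reads
    counts = rng.multinomial(n, lam / lam.sum())
    return CellCountProfile(cell_id=cell_id, values=counts, stage="raw", space=grid)


def simulate_gene_table(
    genome: list[ChromInfo],
    n_genes: int,
    seed: int = 11,
) -> list[GeneLocus]:
    """Random gene loci (spans log-uniform between 5 kb and 300 kb)."""
    rng = np.random.default_rng(seed)
    lengths = np.array([c.length for c in genome], dtype=float)
    genes = []
    for g in range(n_genes):
        ci = int(rng.choice(len(genome), p=lengths / lengths.sum()))
        span = int(np.exp(rng.uniform(np.log(5_000), np.log(300_000))))
        start = int(rng.integers(0, genome[ci].length - span))
        genes.append(GeneLocus(name=f"G{g:04d}", chrom=genome[ci].name,
                               tx_start=start, tx_end=start + span))
    return genes


def simulate_gene_counts(
    truth: TruthProfile,
    genes: list[GeneLocus],
    gene_gc: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    cell_id: str = "cell",
    total_reads: int | None = None,
):
    """Raw counts over extended gene loci from the same WGA noise model.

    When ``total_reads`` is not given, the gene-space total is the genome
    total scaled by the fraction of the genome the extended loci cover,
    mirroring counting gene reads out of the same sequencing run.
    """
    from .normalize import CellCountProfile

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    spans = np.array([g.ext_span for g in genes], dtype=float)
    copy = np.array([truth.copy_at(g.chrom, (g.ext_start + g.ext_end) // 2) for g in genes],
                    dtype=float)
    base = copy * spans * _gc_bias_curve(np.asarray(gene_gc), config.gc_bias)
    lam = _noisy_lambda(base, config, rng)
    if total_reads is None:
        genome_bp = sum(c.length for c in config.genome)
        total_reads = int(round(config.total_reads * spans.sum() / genome_bp))
    counts = rng.multinomial(total_reads, lam / lam.sum())
    return CellCountProfile(cell_id=cell_id, values=counts, stage="raw", space=genes)


DEFAULT_GROUP_EVENTS = {"lineA": 11, "lineB": 30, "lineC": 32}


@dataclass
class SimCohort:
    grid: BinGrid
    config: SimConfig
    wbc: dict                     # cell_id -> CellCountProfile (raw)
    groups: dict                  # group_id -> dict cell_id -> CellCountProfile
    truths: dict                  # group_id -> TruthProfile
    wbc_truth: TruthProfile


def simulate_cohort(
    config: SimConfig | None = None,
    group_events: dict[str, int] | None = None,
    min_flank_bp: int = 12_000_000,
) -> SimCohort:
    """A WBC reference panel plus replicate tumor-like cells per group.

    Deterministic per config.seed: truths, GC track and every cell's counts
    derive from one seed sequence.
    """
    config = config or SimConfig()
    group_events = group_events if group_events is not None else dict(DEFAULT_GROUP_EVENTS)
    grid = make_bin_grid(config.genome, config.bin_width)
    grid.gc = make_bin_gc(grid, seed=config.seed)
    rng = np.random.default_rng([config.seed, 0xC0C0])
    wbc_truth = flat_truth(config.genome)
    wbc = {}
    for i in range(config.n_wbc):
        cid = f"WBC{i + 1:02d}"
        wbc[cid] = simulate_cell_counts(wbc_truth, grid, config, rng, cell_id=cid)
    groups, truths = {}, {}
    for gid, k in group_events.items():
        truths[gid] = simulate_truth(config.genome, k, min_flank_bp, seed=rng)
        cells = {}
        for i in range(config.n_tumor):
            cid = f"{gid}_{i + 1:02d}"
            cells[cid] = simulate_cell_counts(truths[gid], grid, config, rng, cell_id=cid)
        groups[gid] = cells
    return SimCohort(grid=grid, config=config, wbc=wbc, groups=groups,
                     truths=truths, wbc_truth=wbc_truth)
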