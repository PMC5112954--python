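"""Large-scale state transition (LST) genomic-instability scoring.

An LST is a within-chromosome breakpoint between two consecutive segments
that each span at least 10 Mb.  The per-cell LST count is the genomic
instability score; it is summarized per group (mean, sample sd, coefficient
of variation, Student's t against a control group).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .genome import BinGrid, SegmentSet
from .normalize import CellCountProfile, ReferenceProfile, log2_ratio, normalize_cell

DEFAULT_MIN_FLANK_BP = 10_000_000


@dataclass
class InstabilityScore:
    cell_id: str
    lst: int
    n_segments: int
    params: dict = field(default_factory=dict)


@dataclass
class GroupInstabilitySummary:
    group_id: str
    n_cells: int
    mean: float
    sd: float
    cv: float                  # sd / mean, as a fraction
    p_value: float | None = None
    flags: tuple[str, ...] = ()


def count_lst(
    segments: SegmentSet,
    min_flank_bp: int = DEFAULT_MIN_FLANK_BP,
    min_delta_log2: float = 0.0,
) -> InstabilityScore:
    """Count breakpoints whose flanking segments both span >= ``min_flank_bp``.

    ``min_delta_log2`` optionally additionally requires a log2-ratio jump at
    the break (0 by default: every accepted segmentation breakpoint is a
    copy-number break).  Chromosome boundaries never count.
    """
    lst = 0
    for chrom_segs in segments.by_chrom().values():
        for a, b in zip(chrom_segs[:-1], chrom_segs[1:]):
            if a.span >= min_flank_bp and b.span >= min_flank_bp:
                if abs(a.mean_log2 - b.mean_log2) >= min_delta_log2:
                    lst += 1
    return InstabilityScore(
        cell_id=segments.cell_id,
        lst=lst,
        n_segments=len(segments.segments),
        params={"min_flank_bp": min_flank_bp, "min_delta_log2": min_delta_log2},
    )


def coefficient_of_variation(mean: float, sd: float) -> float:
    """cv = sd / mean (returns NaN when the mean is 0)."""
    return sd / mean if mean != 0 else float("nan")


def summarize_group(
    scores: list[InstabilityScore],
    control: list[InstabilityScore] | None = None,
    group_id: str = "",
    equal_variance: bool = True,
) -> GroupInstabilitySummary:
    """Mean, sample sd, cv and (optionally) a two-sided Student's t p vs control."""
    vals = np.array([s.lst for s in scores], dtype=float)
    flags: list[str] = []
    if len(vals) < 2:
        flags.append("sd undefined (n < 2)")
        sd = float("nan")
    else:
        sd = float(vals.std(ddof=1))
    mean = float(vals.mean())
    p = None
    if control:
        ctrl = np.array([s.lst for s in control], dtype=float)
        if len(vals) >= 2 and len(ctrl) >= 2:
            p = student_t_pvalue(vals, ctrl, equal_variance=equal_variance)
    return GroupInstabilitySummary(
        group_id=group_id,
        n_cells=len(vals),
        mean=mean,
        sd=sd,
        cv=coefficient_of_variation(mean, sd),
        p_value=p,
        flags=tuple(flags),
    )


def student_t_pvalue(x, y, equal_variance: bool = True) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    res = sps.ttest_ind(x, y, equal_var=equal_variance)
    return float(res.pvalue)


def lst_stability_curve(
    counts: CellCountProfile,
    grid: BinGrid,
    reference: ReferenceProfile,
    fractions: list[float],
    params=None,
    seed: int = 1,
    min_flank_bp: int = DEFAULT_MIN_FLANK_BP,
) -> list[tuple[int, int]]:
    """Down-sampling titration: (total_reads, lst) after re-running the pipeline.

    Each fraction binomially thins the raw counts (fraction 1.0 reuses them
    unchanged), renormalizes against the fixed WBC reference, re-segments and
    re-counts LSTs.  Mirrors the in-silico minimal-depth experiment.
    """
    from .qc import downsample_counts
    from .segment import SegmentationParams, segment_cell

    params = params or SegmentationParams()
    rng = np.random.default_rng(seed)
    rows: list[tuple[int, int]] = []
    auto = grid.autosome_mask()
    for frac in fractions:
        sub = counts if frac == 1.0 else downsample_counts(
            counts, frac, seed=int(rng.integers(2**31 - 1))
        )
        norm = normalize_cell(sub, gc=grid.gc)
        lr = log2_ratio(norm, reference, autosome_mask=auto)
        segs = segment_cell(lr, grid, params)
        score = count_lst(segs, min_flank_bp=min_flank_bp)
        rows.append((int(sub.total), score.lst))
    return rows
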