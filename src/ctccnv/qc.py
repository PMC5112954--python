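"""Post-sequencing quality control and count-level down-sampling.

Cells must clear a minimum-read floor (> 350,000 sequencing reads, the
depth at which instability scores were found to stabilize) and a library-
complexity metric: the ratio of absolute LOESS residuals (counts vs GC) over
total sequencing reads in millions.  The residual-over-reads formula is one
defensible reading of an ambiguously published definition, so the threshold
and its comparison direction are configuration, and the formula is echoed in
the report metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import BinGrid
from .normalize import CellCountProfile

MIN_READS = 350_000
RATIO_THRESHOLD = 1.9
RATIO_FORMULA = "sum(|count_i - loess(count~gc)_i|) / (total_reads / 1e6)"


@dataclass
class QCReport:
    cell_id: str
    total_reads: int
    residual_over_reads_ratio: float
    passed: bool
    reasons: tuple[str, ...]
    thresholds: dict = field(default_factory=dict)
    mapq_pass_fraction: float = float("nan")
    duplicate_fraction: float = float("nan")
    metadata: dict = field(default_factory=dict)


def downsample_counts(profile: CellCountProfile, fraction: float, seed: int = 1) -> CellCountProfile:
    """Binomially thin raw counts: count_i -> Binomial(count_i, fraction).

    The count-space equivalent of random read subsampling; the expected total
    is fraction x the original total.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if profile.stage != "raw":
        raise ValueError("downsampling operates on raw counts")
    if fraction == 1.0:
        return CellCountProfile(profile.cell_id, profile.values.copy(), "raw", profile.space)
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(profile.values.astype(np.int64), fraction)
    return CellCountProfile(profile.cell_id, thinned, "raw", profile.space)


def residual_over_reads_ratio(
    profile: CellCountProfile,
    grid: BinGrid,
    span: float = 0.3,
) -> float:
    """Sum of absolute LOESS(count ~ GC) residuals over total reads in millions."""
    gc = grid.gc
    v = profile.values
    usable = np.isfinite(gc)
    if usable.sum() < 100:
        return float("nan")
    total = v.sum()
    if total <= 0:
        return float("nan")
    fitted = lowess(v[usable], gc[usable], frac=span, return_sorted=False)
    resid = np.abs(v[usable] - fitted)
    return float(resid.sum() / (total / 1e6))


def qc_cell(
    profile: CellCountProfile,
    grid: BinGrid,
    min_reads: int = MIN_READS,
    ratio_threshold: float = RATIO_THRESHOLD,
    ratio_direction: str = "greater",
    span: float = 0.3,
) -> QCReport:
    """Pass/fail QC with enumerated reasons.  Both thresholds are strict."""
    total = int(profile.values.sum())
    ratio = residual_over_reads_ratio(profile, grid, span=span)
    reasons: list[str] = []
    if not total > min_reads:
        reasons.append("min_reads")
    if np.isnan(ratio):
        reasons.append("ratio_unevaluable")
    else:
        ok = ratio > ratio_threshold if ratio_direction == "greater" else ratio < ratio_threshold
        if not ok:
            reasons.append("residual_over_reads_ratio")
    return QCReport(
        cell_id=profile.cell_id,
        total_reads=total,
        residual_over_reads_ratio=ratio,
        passed=not reasons,
        reasons=tuple(reasons),
        thresholds={"min_reads": min_reads, "ratio_threshold": ratio_threshold,
                    "ratio_direction": ratio_direction},
        metadata={"ratio_formula": RATIO_FORMULA},
    )
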