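"""Count normalization against a white-blood-cell universal reference.

Each cell's binned (or gene-level) raw counts are scaled to a total of one
million, corrected for GC bias with a LOESS fit, and expressed as log2
ratios against the per-interval median of a panel of diploid WBC controls.
Low-coverage intervals (reference median below a threshold: 100 normalized
reads for 1-Mb bins, 10 for gene loci) are masked out of all downstream
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

TOTAL = 1_000_000.0
DEFAULT_EPSILON = 0.5
DEFAULT_GC_SPAN = 0.3
BIN_MIN_MEDIAN = 100.0
GENE_MIN_MEDIAN = 10.0


class NormalizationError(ValueError):
    pass


@dataclass
class CellCountProfile:
    """One cell's counts over an interval space (bin grid or gene set)."""

    cell_id: str
    values: np.ndarray
    stage: str = "raw"          # raw | scaled | gc_adjusted
    space: object = None        # BinGrid or list[GeneLocus]; optional

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise NormalizationError(f"cell {self.cell_id}: negative counts")

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class ReferenceProfile:
    """Per-interval median/mean/sd across WBC control cells, plus a usability mask."""

    median: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_controls: int
    mask: np.ndarray            # True = usable
    space: object = None

    @property
    def n_intervals(self) -> int:
        return len(self.median)


@dataclass
class LogRatioProfile:
    cell_id: str
    log2_ratio: np.ndarray      # NaN on masked/excluded intervals
    valid: np.ndarray           # bool, True where log2_ratio is defined
    center_offset: float = 0.0
    space: object = None


def scale_to_million(profile: CellCountProfile) -> CellCountProfile:
    """Scale counts proportionally so they sum to one million."""
    total = profile.total
    if total <= 0:
        raise NormalizationError(f"cell {profile.cell_id}: empty cell (total count 0)")
    return CellCountProfile(
        cell_id=profile.cell_id,
        values=profile.values * (TOTAL / total),
        stage="scaled",
        space=profile.space,
    )


def gc_adjust(
    profile: CellCountProfile,
    gc: np.ndarray,
    span: float = DEFAULT_GC_SPAN,
) -> CellCountProfile:
    """Remove GC bias by dividing through a LOESS fit of counts vs GC.

    The curve f(gc) is fitted over intervals with known GC and nonzero
    counts; each such value is multiplied by median(f)/f(gc_i), intervals
    with missing GC pass through unchanged, and the whole profile is
    rescaled to a one-million total.
    """
    gc = np.asarray(gc, dtype=float)
    v = profile.values.copy()
    usable = np.isfinite(gc) & (v > 0)
    if usable.sum() < 20:
        raise NormalizationError(
            f"cell {profile.cell_id}: need >=20 usable intervals for GC fitting"
        )
    if np.ptp(gc[usable]) == 0:
        warnings.warn("degenerate GC (all identical); GC adjustment skipped")
        out_values = v
    else:
        fitted = lowess(v[usable], gc[usable], frac=span, return_sorted=False)
        ok = fitted > 0
        factor = np.ones(usable.sum())
        factor[ok] = np.median(fitted[ok]) / fitted[ok]
        out_values = v
        out_values[usable] = v[usable] * factor
    out_values *= TOTAL / out_values.sum()
    return CellCountProfile(
        cell_id=profile.cell_id, values=out_values, stage="gc_adjusted", space=profile.space
    )


def build_reference(controls: list[CellCountProfile]) -> ReferenceProfile:
    """Per-interval median, mean and sample sd across >=2 control cells."""
    if len(controls) < 2:
        raise NormalizationError("need at least 2 control cells to build a reference")
    n = {len(c.values) for c in controls}
    if len(n) != 1:
        raise NormalizationError("controls live on different interval spaces")
    mat = np.vstack([c.values for c in controls])
    return ReferenceProfile(
        median=np.median(mat, axis=0),
        mean=mat.mean(axis=0),
        sd=mat.std(axis=0, ddof=1),
        n_controls=len(controls),
        mask=np.ones(mat.shape[1], dtype=bool),
        space=controls[0].space,
    )


def mask_low_coverage(ref: ReferenceProfile, min_median: float = BIN_MIN_MEDIAN) -> ReferenceProfile:
    """Mask intervals whose control median falls below ``min_median``."""
    if min_median < 0:
        raise NormalizationError("min_median must be >= 0")
    return ReferenceProfile(
        median=ref.median,
        mean=ref.mean,
        sd=ref.sd,
        n_controls=ref.n_controls,
        mask=ref.mask & (ref.median >= min_median),
        space=ref.space,
    )


def log2_ratio(
    cell: CellCountProfile,
    ref: ReferenceProfile,
    recenter: bool = True,
    epsilon: float = DEFAULT_EPSILON,
    autosome_mask: np.ndarray | None = None,
) -> LogRatioProfile:
    """Per-interval log2((cell + eps) / (ref_median + eps)) on usable intervals.

    With ``recenter`` the per-cell median over autosomal usable intervals is
    subtracted, so that the bulk of the genome sits at log2 ratio 0 within
    each cell (most-of-the-genome baseline).
    """
    if len(cell.values) != ref.n_intervals:
        raise NormalizationError("cell and reference interval spaces differ")
    valid = ref.mask & ~((cell.values == 0) & (ref.median == 0))
    if not valid.any():
        raise NormalizationError(f"cell {cell.cell_id}: no usable intervals")
    lr = np.full(ref.n_intervals, np.nan)
    lr[valid] = np.log2((cell.values[valid] + epsilon) / (ref.median[valid] + epsilon))
    offset = 0.0
    if recenter:
        sel = valid if autosome_mask is None else (valid & autosome_mask)
        if not sel.any():
            sel = valid
        offset = float(np.median(lr[sel]))
        lr[valid] -= offset
    return LogRatioProfile(
        cell_id=cell.cell_id, log2_ratio=lr, valid=valid, center_offset=offset, space=cell.space
    )


def normalize_cell(
    profile: CellCountProfile,
    gc: np.ndarray | None = None,
    span: float = DEFAULT_GC_SPAN,
) -> CellCountProfile:
    """Convenience: scale to 1e6 then GC-adjust (when GC is available)."""
    scaled = scale_to_million(profile)
    if gc is None or not np.isfinite(gc).any():
        return scaled
    return gc_adjust(scaled, gc, span=span)
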