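"""Circular binary segmentation (CBS) of per-cell log2-ratio profiles.

The change-point statistic is the classical circular-arc two-sample t:
for an arc x[i:j] against its complement on the circle,

    T(i, j) = (mean_arc - mean_comp) / sqrt(s2p * (1/k + 1/(n-k)))

with pooled within-group variance s2p and arc length k = j - i.  Because
T(arc) = -T(complement), scanning all linear windows (i, j) covers every
circular arc.  A split is accepted when the permutation p-value of the
maximizing arc falls below alpha, and the algorithm recurses on the
resulting (up to three) regions.

The permutation test is evaluated sequentially in blocks: it stops early
either when the exceedance count already guarantees p >= alpha (exact
curtailment) or when a Clopper-Pearson 99.9% bound on the exceedance
probability decides the comparison with alpha.  The stopping rules
reproduce the full-run decision; they only save permutations.  Each
recursion node draws its permutations from an RNG keyed on (seed, cell,
chromosome, lo, hi), so decisions do not depend on the recursion path and
lowering alpha can only remove splits.

Accepted cuts are then refined (re-located as the best binary split of
their bracketing region) and validated (each must be a significant binary
change-point there at alpha/2); cuts that do not stand on their own are
dropped.  This suppresses the spurious short arcs and edge staircases that
joint arc estimation otherwise accumulates across a genome's recursion.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist

from .genome import BinGrid, Segment, SegmentSet
from .normalize import LogRatioProfile

_BLOCK = 256
_REJECT_ETA = 1e-3


@dataclass
class SegmentationParams:
    alpha: float = 0.05
    n_perm: int = 10_000
    min_width: int = 2
    seed: int = 1

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")


def cbs_statistic(values: np.ndarray, i: int, j: int) -> float:
    """|T| for the arc values[i:j] vs its complement (pooled-variance t form)."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if not (0 <= i < j <= n):
        raise ValueError("need 0 <= i < j <= n")
    k = j - i
    if k == n:
        raise ValueError("arc complement is empty")
    s = x.sum()
    q = (x * x).sum()
    w = x[i:j].sum()
    return float(_tstat(w, k, s, q, n))


def _tstat(w, k, s, q, n):
    """Vectorized |T| from arc sum w and length k given totals (s, q, n)."""
    m1 = w / k
    m2 = (s - w) / (n - k)
    ssw = q - k * m1 * m1 - (n - k) * m2 * m2
    df = max(n - 2, 1)
    # within-group sums of squares at rounding level of q are zero variance
    ssw = np.where(ssw < 1e-12 * max(abs(q), 1.0), 0.0, ssw)
    s2p = np.maximum(ssw, 0.0) / df
    se = np.sqrt(s2p * (1.0 / k + 1.0 / (n - k)))
    diff = np.abs(m1 - m2)
    # float-rounding guard: a "difference" at machine epsilon of the data
    # scale is no difference (constant input must yield statistic 0)
    tiny = 1e-9 * (np.abs(m1) + np.abs(m2) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.where(diff > tiny, np.inf, 0.0))
    return t


def _admissible(n: int, k: int, min_width: int) -> np.ndarray:
    """Valid arc start positions i for arc length k: each flank empty or >= min_width.

    Keeps every emitted segment at least min_width bins wide (whole-region
    segments aside), matching the minimum-marker convention.
    """
    i = np.arange(n - k + 1)
    left_ok = (i == 0) | (i >= min_width)
    right = n - k - i
    right_ok = (right == 0) | (right >= min_width)
    return left_ok & right_ok


def max_arc(values: np.ndarray, min_width: int = 2) -> tuple[int, int, float]:
    """Arc (i*, j*) maximizing |T|; ties broken by smallest i, then smallest j."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2 * min_width:
        raise ValueError(f"need at least {2 * min_width} values")
    s = x.sum()
    q = (x * x).sum()
    cs = np.concatenate([[0.0], np.cumsum(x)])
    best = (-1.0, n, n)  # (T, i, j) with lexicographic preference on (i, j)
    for k in range(min_width, n - min_width + 1):
        ok = _admissible(n, k, min_width)
        if not ok.any():
            continue
        w = cs[k:] - cs[:-k]             # arc sums for i = 0 .. n-k
        t = np.where(ok, _tstat(w, k, s, q, n), -np.inf)
        tm = t.max()
        if tm > best[0]:
            i = int(np.argmax(t))
            best = (float(tm), i, i + k)
        elif tm == best[0]:
            i = int(np.argmax(t))
            if (i, i + k) < (best[1], best[2]):
                best = (float(tm), i, i + k)
    return best[1], best[2], best[0]


def _perm_max(x_blocks: np.ndarray, s: float, q: float, min_width: int) -> np.ndarray:
    """Max |T| over all admissible arcs, per row of a (B, n) permutation block."""
    B, n = x_blocks.shape
    cs = np.concatenate([np.zeros((B, 1)), np.cumsum(x_blocks, axis=1)], axis=1)
    out = np.zeros(B)
    for k in range(min_width, n - min_width + 1):
        ok = _admissible(n, k, min_width)
        if not ok.any():
            continue
        w = cs[:, k:][:, ok] - cs[:, :-k][:, ok]
        t = _tstat(w, k, s, q, n)
        np.maximum(out, t.max(axis=1), out=out)
    return out


def permutation_pvalue(
    values: np.ndarray,
    t_star: float,
    params: SegmentationParams,
    rng: np.random.Generator | None = None,
    early_stop: bool = True,
) -> float:
    """p = (1 + #{perm max |T| >= T*}) / (n_perm + 1), with optional sequential stopping.

    When stopped early the estimate (1 + count) / (m + 1) over the m
    permutations actually drawn is returned; the accept/reject decision at
    ``alpha`` is unchanged by the stopping rules.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    s = x.sum()
    q = (x * x).sum()
    accept_count = int(np.ceil(params.alpha * (params.n_perm + 1)))  # count => p >= alpha
    count = 0
    done = 0
    while done < params.n_perm:
        b = min(_BLOCK, params.n_perm - done)
        perms = rng.permuted(np.broadcast_to(x, (b, n)).copy(), axis=1)
        stats = _perm_max(perms, s, q, params.min_width)
        count += int((stats >= t_star).sum())
        done += b
        if early_stop:
            if count >= accept_count:
                break
            if done >= _BLOCK and count > 0:
                # Clopper-Pearson lower bound: p provably above alpha -> accept
                lcb = beta_dist.ppf(_REJECT_ETA, count, done - count + 1)
                if lcb > params.alpha:
                    break
            # Clopper-Pearson upper bound: p provably below alpha -> reject
            ucb = beta_dist.ppf(1 - _REJECT_ETA, count + 1, max(done - count, 1))
            if done >= _BLOCK and ucb < params.alpha:
                break
    return (1 + count) / (done + 1)


def _node_rng(seed: int, cell_key: int, chrom_index: int, lo: int, hi: int) -> np.random.Generator:
    """Permutation RNG keyed on (seed, cell, chromosome, node range).

    Path-independent: a node's permutations do not depend on how the
    recursion reached it, so decisions are reproducible and nested in alpha;
    keying on the cell id decorrelates permutation noise across cells run
    under one seed.
    """
    return np.random.default_rng([seed & 0x7FFFFFFF, cell_key, chrom_index, lo, hi])


def _perm_max_binary(x_blocks: np.ndarray, s: float, q: float, min_width: int) -> np.ndarray:
    """Max binary-split |t| per row of a (B, n) permutation block."""
    B, n = x_blocks.shape
    cs = np.cumsum(x_blocks, axis=1)
    c = np.arange(min_width, n - min_width + 1)
    t = _tstat(cs[:, c - 1], c, s, q, n)
    return t.max(axis=1)


def _validate_cut(
    x: np.ndarray,
    lo: int,
    hi: int,
    cut: int,
    params: SegmentationParams,
    rng: np.random.Generator,
    level: float | None = None,
) -> bool:
    """Is ``cut`` a significant binary change-point within x[lo:hi]?

    Used on the two cuts of an accepted ternary split: the split itself
    stands, but each change-point must hold up as a binary change-point in
    its bracketing region, which prunes spurious arcs picked up jointly with
    a real breakpoint.  The two tests of one split form a family, so each
    runs at half the split alpha.
    """
    alpha = params.alpha if level is None else level
    sub = x[lo:hi]
    n = len(sub)
    if n < 2 * params.min_width:
        return False
    s = sub.sum()
    q = (sub * sub).sum()
    c = cut - lo
    t_obs = float(_tstat(np.cumsum(sub)[c - 1], c, s, q, n))
    accept_count = int(np.ceil(alpha * (params.n_perm + 1)))
    count = 0
    done = 0
    while done < params.n_perm:
        b = min(_BLOCK * 4, params.n_perm - done)
        perms = rng.permuted(np.broadcast_to(sub, (b, n)).copy(), axis=1)
        count += int((_perm_max_binary(perms, s, q, params.min_width) >= t_obs).sum())
        done += b
        if count >= accept_count:
            return False
        if count > 0 and beta_dist.ppf(_REJECT_ETA, count, done - count + 1) > alpha:
            return False
        if beta_dist.ppf(1 - _REJECT_ETA, count + 1, max(done - count, 1)) < alpha:
            return True
    return (1 + count) / (done + 1) < alpha


def _refine_cut(x: np.ndarray, lo: int, hi: int, guess: int, min_width: int) -> int:
    """Re-locate a single change-point between lo and hi by maximizing the binary |t|.

    The circular-arc search picks the two cut positions jointly, which can
    leave either one a bin or two off; each accepted cut is therefore
    re-estimated as the best binary split of its flanking region before
    recursion, so children do not inherit residual steps at their edges.
    """
    n = hi - lo
    if n < 2 * min_width:
        return guess
    sub = x[lo:hi]
    s = sub.sum()
    q = (sub * sub).sum()
    cs = np.concatenate([[0.0], np.cumsum(sub)])
    c = np.arange(min_width, n - min_width + 1)
    t = _tstat(cs[c], c, s, q, n)
    best = int(c[np.argmax(t)])
    return lo + best


def _segment_vector(
    x: np.ndarray, params: SegmentationParams, chrom_index: int, cell_key: int = 0
) -> list[tuple[int, int]]:
    """Recursive CBS over a usable-bin vector; returns (lo, hi) index ranges."""
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * params.min_width:
            out.append((lo, hi))
            return
        sub = x[lo:hi]
        if np.ptp(sub) == 0:
            out.append((lo, hi))
            return
        i, j, t_star = max_arc(sub, params.min_width)
        if t_star <= 0:
            out.append((lo, hi))
            return
        rng = _node_rng(params.seed, cell_key, chrom_index, lo, hi)
        p = permutation_pvalue(sub, t_star, params, rng=rng)
        if p >= params.alpha:
            out.append((lo, hi))
            return
        cuts = [c for c in (i, j) if 0 < c < n]
        if len(cuts) == 2:
            c1 = _refine_cut(x, lo, lo + cuts[1], lo + cuts[0], params.min_width) - lo
            c2 = _refine_cut(x, lo + c1, hi, lo + cuts[1], params.min_width) - lo
            cuts = sorted({c for c in (c1, c2) if 0 < c < n})
            if len(cuts) == 2:
                half = params.alpha / 2
                v1 = _validate_cut(x, lo, lo + cuts[1], lo + cuts[0], params,
                                   _node_rng(params.seed, cell_key, chrom_index + 1000,
                                             lo, lo + cuts[0]), level=half)
                v2 = _validate_cut(x, lo + cuts[0], hi, lo + cuts[1], params,
                                   _node_rng(params.seed, cell_key, chrom_index + 1000,
                                             lo + cuts[1], hi), level=half)
                if not (v1 and v2):
                    # keep only change-points that stand on their own; a
                    # jointly-significant arc with no defensible cut is noise
                    cuts = [c for c, v in zip(cuts, (v1, v2)) if v]
                    if not cuts:
                        out.append((lo, hi))
                        return
        elif cuts:
            c = _refine_cut(x, lo, hi, lo + cuts[0], params.min_width) - lo
            ok = _validate_cut(x, lo, hi, lo + c, params,
                               _node_rng(params.seed, cell_key, chrom_index + 1000,
                                         lo, lo + c), level=params.alpha / 2)
            if not ok:
                out.append((lo, hi))
                return
            cuts = [c]
        pieces = []
        prev = 0
        for c in cuts:
            pieces.append((lo + prev, lo + c))
            prev = c
        pieces.append((lo + prev, hi))
        for a, b in pieces:
            recurse(a, b)

    recurse(0, len(x))
    out.sort()
    return out


def segment_cell(
    profile: LogRatioProfile,
    grid: BinGrid,
    params: SegmentationParams | None = None,
) -> SegmentSet:
    """Segment each chromosome's usable log2-ratio vector with recursive CBS.

    Masked bins are bridged: segmentation runs on the compressed usable-bin
    vector and segment boundaries in bp are taken midway across masked gaps,
    so segments partition the usable span of each chromosome.
    """
    params = params or SegmentationParams()
    cell_key = zlib.crc32(profile.cell_id.encode())
    segments: list[Segment] = []
    slices = grid.chrom_slices()
    for ci, (chrom, sl) in enumerate(slices.items()):
        valid = profile.valid[sl]
        idx = np.where(valid)[0]
        if len(idx) == 0:
            continue
        x = profile.log2_ratio[sl][idx]
        starts = grid.start[sl][idx]
        ends = grid.end[sl][idx]
        if len(x) < 2 * params.min_width:
            segments.append(
                Segment(profile.cell_id, chrom, int(starts[0]), int(ends[-1]),
                        len(x), float(np.mean(x)))
            )
            continue
        for lo, hi in _segment_vector(x, params, ci, cell_key):
            # bridge masked gaps: boundary midway between flanking usable bins
            start_bp = int(starts[lo]) if lo == 0 else int((ends[lo - 1] + starts[lo]) // 2)
            end_bp = int(ends[hi - 1]) if hi == len(x) else int((ends[hi - 1] + starts[hi]) // 2)
            segments.append(
                Segment(profile.cell_id, chrom, start_bp, end_bp,
                        hi - lo, float(np.mean(x[lo:hi])))
            )
    return SegmentSet(
        cell_id=profile.cell_id,
        segments=segments,
        params={"alpha": params.alpha, "n_perm": params.n_perm,
                "min_width": params.min_width, "seed": params.seed},
    )
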