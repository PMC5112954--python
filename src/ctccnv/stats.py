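"""Replicate-concordance and comparison statistics.

Absolute Pearson correlation matrices across cell profiles, the top-fraction
link table for circular concordance diagrams, private CNV event rates (the
per-cell false-call proxy), a two-sided Fisher exact test for 2x2 tables and
the two-sample Student's t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class CorrelationMatrix:
    cell_ids: list[str]
    values: np.ndarray          # |r|, symmetric, unit diagonal; NaN where undefined
    flags: tuple[str, ...] = ()


@dataclass
class PrivateEventReport:
    group_id: str
    cell_ids: list[str]
    fractions: np.ndarray       # NaN where a cell had no calls
    mean: float
    min: float
    max: float


def pearson_matrix(profiles: dict[str, np.ndarray]) -> CorrelationMatrix:
    """Pairwise |Pearson r| over pairwise-complete intervals."""
    ids = list(profiles)
    if len(ids) < 2:
        raise ValueError("need at least 2 profiles")
    n = len(ids)
    out = np.full((n, n), np.nan)
    flags: list[str] = []
    vecs = [np.asarray(profiles[c], dtype=float) for c in ids]
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            a, b = vecs[i], vecs[j]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 2 or a[ok].std() == 0 or b[ok].std() == 0:
                flags.append(f"undefined correlation: {ids[i]} vs {ids[j]}")
                continue
            r = np.corrcoef(a[ok], b[ok])[0, 1]
            out[i, j] = out[j, i] = abs(r)
    return CorrelationMatrix(cell_ids=ids, values=out, flags=tuple(flags))


def top_fraction_links(matrix: CorrelationMatrix, fraction: float = 0.25) -> list[tuple[str, str, float]]:
    """Off-diagonal pairs in the top ``fraction`` by |r| (count rounded up)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(matrix.cell_ids)
    pairs = [
        (i, j, matrix.values[i, j])
        for i in range(n) for j in range(i + 1, n)
        if np.isfinite(matrix.values[i, j])
    ]
    k = math.ceil(fraction * len(pairs))
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    return [(matrix.cell_ids[i], matrix.cell_ids[j], r) for i, j, r in pairs[:k]]


def private_event_rate(
    call_sets: dict[str, set],
    group_id: str = "",
) -> PrivateEventReport:
    """Per-cell fraction of altered-gene calls seen in no other cell of the group.

    A call is identified by (gene, direction); cells with zero calls get a
    NaN fraction (flagged by exclusion from the mean).
    """
    if len(call_sets) < 2:
        raise ValueError("need at least 2 cells per group")
    ids = list(call_sets)
    fractions = np.full(len(ids), np.nan)
    for i, cid in enumerate(ids):
        calls = call_sets[cid]
        if not calls:
            continue
        others = set().union(*(call_sets[c] for c in ids if c != cid))
        fractions[i] = len(calls - others) / len(calls)
    defined = fractions[np.isfinite(fractions)]
    return PrivateEventReport(
        group_id=group_id,
        cell_ids=ids,
        fractions=fractions,
        mean=float(defined.mean()) if len(defined) else float("nan"),
        min=float(defined.min()) if len(defined) else float("nan"),
        max=float(defined.max()) if len(defined) else float("nan"),
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities <= P(observed).

    Computed by enumerating all tables with the observed margins.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0

    def log_p(x: int) -> float:
        # hypergeometric pmf on log scale for table top-left entry x
        return (
            _lchoose(r1, x) + _lchoose(n - r1, c1 - x) - _lchoose(n, c1)
        )

    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    lp_obs = log_p(a)
    tol = 1e-7
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_p(x)
        if lp <= lp_obs + tol:
            total += math.exp(lp)
    return min(total, 1.0)


def _lchoose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def student_t_two_sample(x, y, equal_variance: bool = True) -> float:
    """Two-sided two-sample Student's t p-value (pooled variance by default)."""
    from .instability import student_t_pvalue

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    return student_t_pvalue(x, y, equal_variance=equal_variance)
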