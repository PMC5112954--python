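"""End-to-end benchmark experiments exercising the full pipeline.

Each function generates its inputs with the synthetic WGA generator (or uses
published per-patient count tables as printed inputs), runs the pipeline and
returns summary numbers.  They are shared by the acceptance checks and the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import fish as fishmod
from . import genecnv, normalize, simulate, stats
from .genome import ChromInfo
from .instability import coefficient_of_variation, count_lst, lst_stability_curve
from .segment import SegmentationParams, max_arc, permutation_pvalue, segment_cell, _node_rng

# ---------------------------------------------------------------------------
# Published per-patient tables (inputs, as printed)

# per patient: (n deleted CTCs, n evaluated CTCs) from the CNV pipeline
PATIENT_CNV_PTEN = {
    "1": (5, 9), "2": (3, 16), "3": (0, 17), "4": (0, 2),
    "5": (1, 3), "6": (1, 5), "7": (5, 15),
}

# per patient: (n HO-loss, n HE-loss, n non-deleted) FISH cells and the
# published patient-level FISH call
PATIENT_FISH_PTEN = {
    "1": ((5, 0, 63), "HO_loss"),
    "2": ((0, 44, 15), "HE_loss"),
    "3": ((0, 0, 27), "non_deleted"),
    "4": ((0, 0, 5), "non_deleted"),
    "5": ((0, 1, 18), "non_deleted"),
    "6": ((1, 0, 6), "HO_loss"),
    "7": ((0, 0, 44), "non_deleted"),
}

# patient 5: deleted / non-deleted by FISH (1/19) vs by CNV (1/3)
PATIENT5_TABLE = [[1, 18], [1, 2]]

# cell-line instability summary row for PC3: sample mean and sd of LST scores
PC3_LST_MEAN, PC3_LST_SD = 30.1, 6.0


def fisher_patient5() -> float:
    """Two-sided Fisher exact p for the patient-5 FISH vs CNV 2x2 table."""
    return stats.fisher_exact_2x2(PATIENT5_TABLE)


def pten_loss_patients(min_cells: int = 1) -> list[str]:
    """Patients called PTEN loss from the printed per-patient deleted-CTC counts.

    ``min_cells=1`` is the as-applied patient rule of the published table.
    """
    called = []
    for pid, (n_del, n_eval) in PATIENT_CNV_PTEN.items():
        cells = [
            genecnv.GeneZScore(f"p{pid}c{i}", "PTEN", 0.0, 0.0, 1.0,
                               -4.0 if i < n_del else 0.0, 0.0,
                               "deleted" if i < n_del else "neutral")
            for i in range(n_eval)
        ]
        call = genecnv.call_patient(cells, patient_id=pid, min_cells=min_cells)
        if call.patient_call == "deleted":
            called.append(pid)
    return called


def pc3_cv_percent() -> float:
    """Coefficient of variation (%) of the PC3 LST scores from mean and sd."""
    return 100.0 * coefficient_of_variation(PC3_LST_MEAN, PC3_LST_SD)


def fish_patient_concordance() -> int:
    """How many of the 7 printed FISH patient calls the classifier reproduces."""
    n_match = 0
    for pid, ((n_ho, n_he, n_nd), expected) in PATIENT_FISH_PTEN.items():
        cells = (
            [fishmod.FishCell(f"{pid}ho{i}", 0, 2) for i in range(n_ho)]
            + [fishmod.FishCell(f"{pid}he{i}", 1, 2) for i in range(n_he)]
            + [fishmod.FishCell(f"{pid}nd{i}", 2, 2) for i in range(n_nd)]
        )
        call = fishmod.classify_fish_patient(cells, patient_id=pid)
        n_match += call.patient_call == expected
    return n_match


# ---------------------------------------------------------------------------
# Simulation-based experiments


def _brute_force_max_arc(x: np.ndarray, min_width: int = 2):
    from .segment import cbs_statistic

    n = len(x)
    best = (-1.0, n, n)
    for i in range(n):
        for j in range(i + min_width, n + 1):
            k = j - i
            if k > n - min_width and k != n:
                continue
            if k == n:
                continue
            left, right = i, n - j
            if (0 < left < min_width) or (0 < right < min_width):
                continue
            t = cbs_statistic(x, i, j)
            if t > best[0]:
                best = (t, i, j)
    return best[1], best[2], best[0]


def cbs_oracle_agreement(seed: int, n_cases: int = 300) -> float:
    """Fraction of random small inputs where max_arc matches exhaustive search."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        n = int(rng.integers(4, 13))
        x = np.round(rng.standard_normal(n), 3)
        i, j, t = max_arc(x, 2)
        bi, bj, bt = _brute_force_max_arc(x, 2)
        agree += (i, j) == (bi, bj) or np.isclose(t, bt)
    return agree / n_cases


def cbs_null_split_rate(seed: int, n_trials: int = 500, n: int = 50,
                        alpha: float = 0.05, n_perm: int = 10_000) -> float:
    """Split-acceptance rate of the max-arc permutation test on pure noise."""
    params = SegmentationParams(alpha=alpha, n_perm=n_perm, min_width=2, seed=seed)
    rng = np.random.default_rng(seed)
    rejections = 0
    for trial in range(n_trials):
        x = rng.standard_normal(n)
        _, _, t_star = max_arc(x, params.min_width)
        p = permutation_pvalue(x, t_star, params,
                               rng=_node_rng(seed, trial, 0, 0, n))
        rejections += p < params.alpha
    return rejections / n_trials


def _reference_panel(grid, config, rng, n_wbc: int = 15):
    wbc_truth = simulate.flat_truth(config.genome)
    controls = [
        normalize.normalize_cell(
            simulate.simulate_cell_counts(wbc_truth, grid, config, rng, cell_id=f"wbc{i}"),
            gc=grid.gc,
        )
        for i in range(n_wbc)
    ]
    return normalize.mask_low_coverage(normalize.build_reference(controls), 100)


def _pipeline_lst(cell, grid, ref, params, min_flank_bp=10_000_000):
    lr = normalize.log2_ratio(normalize.normalize_cell(cell, gc=grid.gc), ref,
                              autosome_mask=grid.autosome_mask())
    ss = segment_cell(lr, grid, params)
    return count_lst(ss, min_flank_bp=min_flank_bp).lst


def lst_recovery(seed: int, ks=(0, 5, 12, 30), n_reps: int = 20,
                 total_reads: int = 3_000_000, min_flank_bp: int = 12_000_000) -> dict:
    """Full-pipeline LST recovery of implanted breakpoint counts.

    Returns per-k the replicate scores and the fraction recovered within
    +/-10% of k (+/-1 for k <= 5).
    """
    genome = simulate.toy_genome()
    grid = simulate.make_bin_grid(genome)
    grid.gc = simulate.make_bin_gc(grid, seed=seed)
    config = simulate.SimConfig(seed=seed, genome=genome, total_reads=total_reads)
    rng = np.random.default_rng([seed, 1])
    ref = _reference_panel(grid, config, rng)
    out = {}
    for k in ks:
        scores = []
        for r in range(n_reps):
            rng_r = np.random.default_rng([seed, k, r])
            truth = simulate.simulate_truth(genome, k, min_flank_bp, seed=rng_r)
            cell = simulate.simulate_cell_counts(truth, grid, config, rng_r,
                                                 cell_id=f"k{k}r{r}")
            scores.append(_pipeline_lst(cell, grid, ref,
                                        SegmentationParams(seed=seed)))
        band = 1 if k <= 5 else int(0.1 * k)
        frac = float(np.mean([abs(s - k) <= band for s in scores]))
        out[k] = {"scores": scores, "band": band, "fraction_recovered": frac}
    return out


def downsampling_stability(seed: int, n_reps: int = 10, k: int = 12,
                           total_reads: int = 3_000_000) -> dict:
    """Depth titration mirroring the in-silico minimal-depth experiment.

    One tumor-like cell per replicate on an hg38-sized grid; its counts are
    binomially thinned to 50%, ~350K and ~35K reads and the LST score is
    recomputed at each depth against the same full-depth WBC reference.
    """
    genome = simulate.hg38_genome()
    grid = simulate.make_bin_grid(genome)
    grid.gc = simulate.make_bin_gc(grid, seed=seed)
    config = simulate.SimConfig(seed=seed, genome=genome, total_reads=total_reads)
    rng = np.random.default_rng([seed, 2])
    ref = _reference_panel(grid, config, rng)
    fractions = [1.0, 0.5, 350_000 / total_reads, 35_000 / total_reads]
    rows = []
    for r in range(n_reps):
        rng_r = np.random.default_rng([seed, 3, r])
        truth = simulate.simulate_truth(genome, k, 12_000_000, seed=rng_r,
                                        span_max_bp=25_000_000)
        cell = simulate.simulate_cell_counts(truth, grid, config, rng_r,
                                             cell_id=f"ds{r}")
        curve = lst_stability_curve(cell, grid, ref, fractions,
                                    params=SegmentationParams(seed=seed),
                                    seed=seed + r)
        rows.append(curve)
    full = [row[0][1] for row in rows]
    within2_at_350k = [
        all(abs(row[i][1] - row[0][1]) <= 2 for i in (1, 2)) for row in rows
    ]
    dev_gt2_at_35k = [abs(row[3][1] - row[0][1]) > 2 for row in rows]
    return {
        "curves": rows,
        "full_depth_scores": full,
        "fraction_stable_at_350k": float(np.mean(within2_at_350k)),
        "fraction_deviating_at_35k": float(np.mean(dev_gt2_at_35k)),
    }


def gene_false_call_rate(seed: int, n_genes: int = 400, n_cells: int = 20,
                         n_wbc: int = 15) -> dict:
    """|Z| > 3 false-call rate on fully diploid cells vs a simulated WBC reference."""
    genome = simulate.toy_genome()
    config = simulate.SimConfig(seed=seed, genome=genome)
    genes = simulate.simulate_gene_table(genome, n_genes, seed=seed)
    chrom_map = {c.name: c for c in genome}
    genes = [genecnv.extend_gene_span(g, chrom_map[g.chrom]) for g in genes]
    rng = np.random.default_rng([seed, 4])
    gene_gc = np.clip(rng.normal(0.45, 0.06, size=n_genes), 0.30, 0.62)
    truth = simulate.flat_truth(genome)
    controls = [
        normalize.normalize_cell(
            simulate.simulate_gene_counts(truth, genes, gene_gc, config, rng,
                                          cell_id=f"w{i}"),
            gc=gene_gc,
        )
        for i in range(n_wbc)
    ]
    ref = normalize.mask_low_coverage(normalize.build_reference(controls), 10)
    n_false = 0
    n_eval = 0
    for c in range(n_cells):
        cell = normalize.normalize_cell(
            simulate.simulate_gene_counts(truth, genes, gene_gc, config, rng,
                                          cell_id=f"t{c}"),
            gc=gene_gc,
        )
        calls = genecnv.call_cell_genes(cell, ref, genes)
        for g in calls:
            if g.call == "unevaluable":
                continue
            n_eval += 1
            n_false += g.call != "neutral"
    return {"n_evaluated": n_eval, "n_false": n_false,
            "rate_percent": 100.0 * n_false / n_eval}


def wbc_instability(seed: int, n_cells: int = 20, n_wbc: int = 15) -> dict:
    """LST scores of simulated diploid WBC-like cells through the full pipeline."""
    genome = simulate.toy_genome()
    grid = simulate.make_bin_grid(genome)
    grid.gc = simulate.make_bin_gc(grid, seed=seed)
    config = simulate.SimConfig(seed=seed, genome=genome)
    rng = np.random.default_rng([seed, 5])
    ref = _reference_panel(grid, config, rng, n_wbc=n_wbc)
    truth = simulate.flat_truth(genome)
    scores = []
    for c in range(n_cells):
        cell = simulate.simulate_cell_counts(truth, grid, config, rng, cell_id=f"wt{c}")
        scores.append(_pipeline_lst(cell, grid, ref, SegmentationParams(seed=seed)))
    scores = [int(s) for s in scores]
    return {"scores": scores,
            "fraction_le_2": float(np.mean([s <= 2 for s in scores])),
            "mean": float(np.mean(scores))}
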