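"""End-to-end orchestration of the two analysis pipelines.

Pipeline 1 (1-Mb bins): scale to one million -> GC adjust -> WBC reference
(median/mean/sd) -> mask bins with reference median < 100 -> log2 ratio ->
CBS segmentation (alpha = 0.05) -> LST instability score per cell.

Pipeline 2 (gene loci extended to >= 100 kb): same normalization -> mask
genes with reference median < 10 -> Z score per gene -> per-cell calls
(|Z| > 3) -> patient-level aggregation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import genecnv, instability, normalize, segment
from .genome import BinGrid, GeneLocus, SegmentSet


@dataclass
class PipelineConfig:
    bin_width: int = 1_000_000
    bin_min_median: float = 100.0
    gene_min_median: float = 10.0
    gc_span: float = 0.3
    epsilon: float = 0.5
    recenter: bool = True
    alpha: float = 0.05
    n_perm: int = 10_000
    min_width: int = 2
    seed: int = 1
    min_flank_bp: int = 10_000_000
    min_delta_log2: float = 0.0
    z_amp: float = 3.0
    z_del: float = -3.0
    min_cells: int = 2
    min_reads: int = 350_000
    ratio_threshold: float = 1.9

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def segmentation_params(self) -> segment.SegmentationParams:
        return segment.SegmentationParams(
            alpha=self.alpha, n_perm=self.n_perm, min_width=self.min_width, seed=self.seed
        )


def build_masked_reference(
    counts: pd.DataFrame,
    wbc_ids: list[str],
    gc: np.ndarray | None,
    min_median: float,
    config: PipelineConfig,
) -> normalize.ReferenceProfile:
    controls = [
        normalize.normalize_cell(
            normalize.CellCountProfile(c, counts[c].to_numpy(), "raw"), gc=gc, span=config.gc_span
        )
        for c in wbc_ids
    ]
    return normalize.mask_low_coverage(normalize.build_reference(controls), min_median)


def run_pipeline1(
    counts: pd.DataFrame,
    grid: BinGrid,
    wbc_ids: list[str],
    config: PipelineConfig | None = None,
):
    """Binned counts -> SEG segments + LST table.

    ``counts`` is a bins x cells matrix aligned with ``grid``; WBC columns
    build the universal reference and are excluded from the test set.
    Returns (segment sets, lst table DataFrame, log-ratio profiles).
    """
    config = config or PipelineConfig()
    if len(counts) != grid.n_bins:
        raise ValueError("count matrix does not match the bin grid")
    missing = set(wbc_ids) - set(counts.columns)
    if missing:
        raise ValueError(f"WBC ids not in matrix: {sorted(missing)}")
    ref = build_masked_reference(counts, wbc_ids, grid.gc, config.bin_min_median, config)
    params = config.segmentation_params()
    auto = grid.autosome_mask()
    seg_sets: dict[str, SegmentSet] = {}
    profiles: dict[str, normalize.LogRatioProfile] = {}
    rows = []
    for cid in counts.columns:
        if cid in wbc_ids:
            continue
        cell = normalize.normalize_cell(
            normalize.CellCountProfile(cid, counts[cid].to_numpy(), "raw"),
            gc=grid.gc, span=config.gc_span,
        )
        lr = normalize.log2_ratio(cell, ref, recenter=config.recenter,
                                  epsilon=config.epsilon, autosome_mask=auto)
        ss = segment.segment_cell(lr, grid, params)
        score = instability.count_lst(ss, config.min_flank_bp, config.min_delta_log2)
        seg_sets[cid] = ss
        profiles[cid] = lr
        rows.append((cid, score.lst, score.n_segments))
    lst_table = pd.DataFrame(rows, columns=["cell_id", "lst", "n_segments"])
    return seg_sets, lst_table, profiles


def run_pipeline2(
    gene_counts: pd.DataFrame,
    genes: list[GeneLocus],
    wbc_ids: list[str],
    config: PipelineConfig | None = None,
    gene_gc: np.ndarray | None = None,
    patients: dict[str, str] | None = None,
):
    """Gene counts -> per-cell Z-score calls + patient-level calls.

    ``patients`` maps cell_id -> patient_id (default: all test cells belong
    to one patient).  Returns (cell-level DataFrame, patient-level DataFrame).
    """
    config = config or PipelineConfig()
    if len(gene_counts) != len(genes):
        raise ValueError("gene count matrix does not match the gene list")
    ref = build_masked_reference(gene_counts, wbc_ids, gene_gc, config.gene_min_median, config)
    cell_rows = []
    calls_by_patient_gene: dict[tuple[str, str], list] = {}
    for cid in gene_counts.columns:
        if cid in wbc_ids:
            continue
        cell = normalize.normalize_cell(
            normalize.CellCountProfile(cid, gene_counts[cid].to_numpy(), "raw"),
            gc=gene_gc, span=config.gc_span,
        )
        zs = genecnv.call_cell_genes(cell, ref, genes, config.z_amp, config.z_del)
        pid = (patients or {}).get(cid, "patient")
        for g in zs:
            cell_rows.append((cid, pid, g.gene, g.x, g.ref_mean, g.ref_sd, g.z, g.log2, g.call))
            calls_by_patient_gene.setdefault((pid, g.gene), []).append(g)
    cell_table = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "patient_id", "gene", "x", "ref_mean", "ref_sd", "z", "log2", "call"],
    )
    patient_rows = []
    for (pid, gene), zlist in sorted(calls_by_patient_gene.items()):
        if all(z.call == "unevaluable" for z in zlist):
            continue
        pc = genecnv.call_patient(zlist, patient_id=pid, min_cells=config.min_cells)
        patient_rows.append((pid, gene, pc.n_cells_evaluated, pc.n_amplified,
                             pc.n_deleted, pc.patient_call))
    patient_table = pd.DataFrame(
        patient_rows,
        columns=["patient_id", "gene", "n_cells_evaluated", "n_amplified", "n_deleted", "call"],
    )
    return cell_table, patient_table
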