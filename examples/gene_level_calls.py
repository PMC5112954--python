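"""Pipeline 2: gene-level amplification/deletion calls from Z scores.

Simulates gene-interval counts for 15 WBC reference cells and three tumor
cells carrying a homozygous deletion of one gene and an 8-copy amplification
of another, then calls each gene per cell (|Z| > 3) and aggregates to a
patient call (alteration must recur in >= 2 cells).
"""

import numpy as np
import pandas as pd

import ctccnv as cc
from ctccnv.pipeline import PipelineConfig, run_pipeline2

genome = cc.toy_genome()
genes = cc.simulate_gene_table(genome, 120, seed=5)
chrom_map = {c.name: c for c in genome}
genes = [cc.extend_gene_span(g, chrom_map[g.chrom]) for g in genes]
gene_gc = np.clip(np.random.default_rng(5).normal(0.45, 0.05, len(genes)), 0.3, 0.6)

deleted = next(g for g in genes if g.chrom == "chr1")
amplified = next(g for g in genes if g.chrom == "chr3")
tumor_truth = cc.TruthProfile({
    deleted.chrom: [(0, deleted.ext_start, 2),
                    (deleted.ext_start, deleted.ext_end, 0),
                    (deleted.ext_end, chrom_map[deleted.chrom].length, 2)],
    amplified.chrom: [(0, amplified.ext_start, 2),
                      (amplified.ext_start, amplified.ext_end, 8),
                      (amplified.ext_end, chrom_map[amplified.chrom].length, 2)],
})

cfg = cc.SimConfig(seed=5, genome=genome, total_reads=3_000_000)
rng = np.random.default_rng(5)
flat = cc.simulate.flat_truth(genome)
counts = {}
for i in range(15):
    counts[f"w{i}"] = cc.simulate_gene_counts(flat, genes, gene_gc, cfg, rng,
                                              cell_id=f"w{i}").values.astype(int)
for i in range(3):
    counts[f"ctc{i}"] = cc.simulate_gene_counts(tumor_truth, genes, gene_gc, cfg, rng,
                                                cell_id=f"ctc{i}").values.astype(int)
matrix = pd.DataFrame(counts, index=[g.name for g in genes])

cell_table, patient_table = run_pipeline2(
    matrix, genes, [f"w{i}" for i in range(15)], PipelineConfig(min_cells=2),
    gene_gc=gene_gc)

altered = patient_table[patient_table["call"] != "none"]
print(f"truth: {deleted.name} homozygously deleted, {amplified.name} amplified (8 copies)\n")
print(altered.to_string(index=False))
print("\nn_deleted / n_amplified count the cells with |Z| > 3 for that gene;")
print("the patient call requires the alteration in at least two cells.")
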