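"""How many reads does a stable instability score need?

Thins one simulated tumor cell's counts to 50%, ~12% (350K reads) and ~1%
(35K reads) of full depth and recomputes the LST score at each depth.  The
score should hold to within a couple of breaks down to roughly 350K reads
and become unreliable near 35K - the basis of the 350K-read QC floor.
"""

import numpy as np

import ctccnv as cc
from ctccnv.segment import SegmentationParams

genome = cc.hg38_genome()
grid = cc.make_bin_grid(genome)
grid.gc = cc.make_bin_gc(grid, seed=3)
cfg = cc.SimConfig(seed=3, genome=genome, total_reads=3_000_000)
rng = np.random.default_rng(3)

flat = cc.simulate.flat_truth(genome)
controls = [cc.normalize_cell(cc.simulate_cell_counts(flat, grid, cfg, rng,
                                                      cell_id=f"w{i}"), gc=grid.gc)
            for i in range(15)]
reference = cc.mask_low_coverage(cc.build_reference(controls), 100)

truth = cc.simulate_truth(genome, 12, min_flank_bp=12_000_000, seed=rng,
                          span_max_bp=25_000_000)
cell = cc.simulate_cell_counts(truth, grid, cfg, rng, cell_id="tumor")

fractions = [1.0, 0.5, 350_000 / 3_000_000, 35_000 / 3_000_000]
curve = cc.lst_stability_curve(cell, grid, reference, fractions,
                               params=SegmentationParams(seed=3), seed=3)

print(f"truth LST = {truth.truth_lst()}\n")
print(f"{'reads':>10}  lst")
for reads, lst in curve:
    print(f"{reads:>10,}  {lst}")
print("\nScores at >= 350K reads should match full depth to within +-2;")
print("at 35K reads counting noise degrades the segmentation.")
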