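# ctccnv

Copy-number and genomic-instability analysis for single-cell, low-pass
(~0.01×) whole-genome sequencing of whole-genome-amplified cells — built for
circulating tumor cells (CTCs) recovered from patient blood, where each cell
yields only a few hundred thousand usable reads and conventional bulk CNV
callers do not apply.

The package implements two pipelines over per-cell binned read counts,
normalized against a *universal reference* of white-blood-cell (WBC)
controls:

1. **Genomic instability.** Reads are counted in 1-Mb bins, scaled to a
   one-million total, GC-corrected (LOESS), and expressed per bin as
   log2((cell + ε)/(reference median + ε)). Each cell's profile is segmented
   with circular binary segmentation — the maximal circular-arc pooled-t
   statistic, accepted by a permutation test at α = 0.05 and applied
   recursively — and scored by the number of **large-scale state
   transitions (LST)**: breakpoints whose flanking segments both span
   ≥ 10 Mb. The LST count is the per-cell instability score.
2. **Gene-level calls.** Reads are counted over gene loci extended to a
   ≥ 100-kb span, normalized the same way, and standardized per gene against
   the reference: Z = (X − X̄)/S. A cell's gene is *amplified* when Z > 3,
   *deleted* when Z < −3; a patient carries the alteration when it recurs in
   ≥ 2 cells (a ≥ 1-cell rule is also provided).

Around the core: post-sequencing QC (> 350K-read floor and a LOESS
residual-over-reads library-complexity metric), binomial-thinning
down-sampling for depth titrations, replicate-concordance statistics
(absolute Pearson matrices, private-event rates, Fisher's exact test,
Student's t), a PTEN/CEP10 FISH comparator, and a synthetic single-cell WGA
data generator (negative-binomial counts with GC bias and dropout, plus
segmental copy-number truth) so the whole pipeline is testable without any
sequencing data. See `docs/methods.md` for the model details and design
choices.

## Worked example

`examples/instability_pipeline.py` simulates a 1.2-Gb toy genome with eight
WBC reference cells and two groups of three tumor-like cells carrying 2 and
14 implanted breakpoints, then runs the full instability pipeline:

```
truth: stable group has 2 breakpoints, unstable group has 14

    cell_id  lst  n_segments
  stable_01    2           8
  stable_02    2           8
  stable_03    4          12
unstable_01   13          23
unstable_02   13          24
unstable_03   14          22
```

Each row is one cell; `lst` counts chromosomal breaks with ≥ 10-Mb flanks —
the instability score — and sits at or near each group's implanted
breakpoint count (one cell picked up two spurious breaks, the expected
order of segmentation noise at α = 0.05).

`examples/fish_and_concordance.py` scores a patient's FISH signal counts
and compares assays:

```
FISH patient call: non_deleted (1 HE-loss of 19 cells; HE loss needs >= 3)
Fisher exact p (FISH 1/19 vs CNV 1/3 deleted) = 0.2597
```

The other examples cover gene-level amplification/deletion calling
(`gene_level_calls.py`) and the read-depth titration behind the 350K-read
QC floor (`depth_titration.py`). A thin `ctccnv` command-line interface
wraps the same functions for file-based use (`ctccnv --help`).

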