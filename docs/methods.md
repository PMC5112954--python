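# Methods

`ctccnv` analyzes single-cell, low-pass (~0.01x) whole-genome sequencing of
whole-genome-amplified (WGA) cells — typically circulating tumor cells
(CTCs) recovered from blood — for copy-number variation and genomic
instability. Two pipelines share one normalization core:

1. **Instability pipeline** (1-Mb bins): per-cell binned read counts →
   scale to one million total → GC-bias adjustment → log2 ratio against a
   white-blood-cell (WBC) universal reference → circular binary segmentation
   (CBS) → large-scale state transition (LST) count.
2. **Gene pipeline**: reads counted over gene loci extended to ≥ 100 kb →
   same normalization → per-gene Z score against the WBC reference →
   amplification (Z > 3) / deletion (Z < −3) calls per cell → patient-level
   aggregation.

## Normalization and the universal reference

Counts are scaled proportionally to a one-million total so cells of
different depth are comparable. GC bias is removed multiplicatively: a
LOESS curve f(gc) is fitted to scaled counts versus per-interval GC fraction
(span 0.3 by default; fitted on intervals with known GC and nonzero counts),
each value is multiplied by median(f)/f(gc_i), and the profile is rescaled
to one million. Intervals without GC (e.g. all-N sequence) pass through.
Controls are GC-adjusted the same way before the reference is built,
so test/reference ratios compare like with like.

The universal reference is built from ≥ 2 (by design 15) WBC control
cells: per-interval median, mean and sample standard deviation (n−1; with
15 controls the denominator convention is material). The median is the
ratio denominator and drives the low-coverage mask (median < 100 normalized
reads for 1-Mb bins, < 10 for genes); mean and sd feed the gene Z score.

Log2 ratios use a symmetric pseudocount of 0.5 normalized units to avoid
infinities at zero counts; intervals where both cell and reference are zero
are dropped. Each cell is recentered by its median autosomal log2 ratio
(most-of-the-genome baseline), recorded in `center_offset` and switchable
off. The pipeline reports relative copy number only; ploidy estimation,
mappability and replication-timing corrections are out of scope.

## Segmentation

CBS is implemented from first principles. For an arc x[i:j] of a
chromosome's usable-bin vector against its complement on the circle, the
statistic is the pooled-variance two-sample t; scanning all windows (i, j)
covers every circular arc because T(arc) = −T(complement). The maximizing
arc (ties broken toward the smallest i, then j; arcs are admissible only
when each flank is empty or at least `min_width` = 2 bins, so no emitted
segment is narrower than the minimum marker count) is accepted as a split
when its permutation p-value, p = (1 + #{permutation max |T| ≥ T*}) /
(n_perm + 1) with n_perm = 10,000, falls below alpha = 0.05; the recursion
then continues on the resulting regions. Masked bins are bridged:
segmentation runs on the compressed usable vector, and segment boundaries
interpolate to the midpoint across masked gaps, so segments partition each
chromosome's usable span.

Three design choices around the core recursion:

- **Sequential permutation testing.** Permutations are drawn in blocks and
  stopped early when the outcome is decided: exactly, once the exceedance
  count guarantees p ≥ alpha, or via 99.9% Clopper–Pearson bounds on the
  exceedance probability in either direction. Decisions match the full-run
  permutation test (up to the 10⁻³ bound level); only compute is saved.
- **Path-independent randomness.** Each recursion node derives its
  permutation RNG from (seed, cell id, chromosome, node range). Decisions
  therefore do not depend on recursion order, repeated runs are identical,
  and lowering alpha can only remove splits (monotonicity holds exactly).
- **Change-point refinement and validation.** The circular search picks the
  two cut positions of a ternary split jointly, which can leave either one
  a bin or two off and can pair a real breakpoint with a spurious one.
  After a split is accepted, each cut is re-located as the best binary
  split of its bracketing region, and each must then hold up as a
  significant binary change-point there (permutation test at alpha/2,
  treating the split's cuts as a family). Cuts that fail are dropped; a
  split none of whose cuts stands is discarded. This prunes the spurious
  short arcs and edge "staircase" segments that otherwise accumulate at a
  rate of several per genome when many true breakpoints are present, at
  the cost of making the end-to-end splitting behavior mildly conservative
  relative to the nominal per-test alpha (the per-node test itself remains
  exactly calibrated, which is what the calibration check measures).

Refinements specific to DNAcopy — the hybrid tail approximation, undo
steps, outlier smoothing — are intentionally not reproduced, and exact
output parity with DNAcopy is a non-goal.

## LST score

An LST is a within-chromosome breakpoint between consecutive segments that
both span at least `min_flank_bp` = 10 Mb. Chromosome boundaries never
count. By default every accepted breakpoint qualifies regardless of the
log2 jump (`min_delta_log2` = 0); a threshold is available because the
classical definition of a state transition requires a copy-number
difference. No small-segment smoothing is applied before counting (a flag
exists but is off). Group summaries report mean, sample sd, the
coefficient of variation sd/mean, and a two-sided pooled-variance Student's
t against a control group (Welch via flag).

## Gene-level calls

Genes with transcript span < 100 kb are extended symmetrically to a 100-kb
counting span; at chromosome ends the deficit shifts to the other side so
the span is preserved where possible. Overlapping extended loci are counted
independently. Per gene, Z = (X − X̄)/S, where X is the cell's normalized
(GC-adjusted, 1e6-scaled) value and X̄, S the reference mean and sd on the
same scale; cutoffs are strict (amplified iff Z > 3, deleted iff Z < −3);
genes with S = 0 or a masked reference are unevaluable rather than ±∞.
Note the structural consequences: with 15 reference cells the predictive
null distribution of Z is t₁₄-like, so the two-sided rate of |Z| > 3 on
truly diploid cells is ≈ 1.2% rather than the Gaussian 0.27%; and a
homozygous deletion (X = 0, Z = −X̄/S) is uncallable for genes whose
estimated reference coefficient of variation exceeds 1/3 (~3% of genes
under the default noise model).

At the patient level an alteration must recur in `min_cells` cells. The
API default is 2, the stated recurrence rule; the published per-patient
PTEN table is reproduced with `min_cells = 1` (two of its loss calls rest
on a single deleted CTC), and both settings are first-class.

## QC and down-sampling

A cell passes QC when it has strictly more than 350,000 reads — the depth
at which the instability score stabilizes in the titration below — and its
residual-over-reads ratio clears 1.9. The published description of that
second metric is ambiguous (what is fitted against what, and why larger
residuals indicate better library complexity, are unstated), so this
package implements one defensible reading — sum of absolute residuals of a
LOESS fit of raw counts versus GC, divided by total reads in millions —
echoes the formula in the report metadata, and exposes both the threshold
and the comparison direction as configuration.

Down-sampling is binomial thinning of counts, Binomial(count_i, fraction),
the count-space equivalent of random read subsampling; thinning by f₁ then
f₂ is distributionally thinning by f₁f₂. Read-level subsampling of BAMs is
deliberately not needed by any test.

## Concordance statistics

Absolute Pearson correlations between cell profiles over pairwise-complete
intervals (zero-variance profiles flagged); the top-fraction link table
rounds the pair count up so small matrices keep at least one link. Private
CNV events are per-cell altered-gene calls (gene + direction) seen in no
other cell of the group — a false-call proxy. Fisher's exact test sums
hypergeometric probabilities ≤ that of the observed table (the standard
two-sided convention, which reproduces the published patient-5 p-value of
0.2597); Student's t is the pooled two-sample test.

## FISH comparator

Per cell: homozygous loss (PTEN = 0, CEP10 ≥ 1), hemizygous loss (PTEN = 1,
CEP10 ≥ 1), non-deleted (PTEN ≥ 2, CEP10 ≥ 1), unevaluable without a CEP10
signal. Patient calls: homozygous loss from ≥ 1 HO cell, else hemizygous
loss from ≥ 3 HE cells, else non-deleted. The underlying clinical scoring
algorithm is not public; these defaults reproduce every published patient
row and are configurable. A gain predicate exists but is disabled in
patient calling because no printed rule defines it.

## Synthetic data generator

The generator emulates single-cell WGA sequencing well enough to exercise
every stage with known truth:

- **Truth**: each chromosome receiving b breakpoints is carved into b+1
  alternating diploid/non-diploid segments (non-diploid copy drawn from
  {1, 4}, so adjacent log2 differences are ≥ 0.8); every segment spans at
  least `min_flank_bp` (default 12 Mb, comfortably above the 10-Mb LST
  floor so bin-edge rounding and boundary error cannot disqualify a true
  breakpoint), and a clustered mode bounds interior spans (used for the
  depth titration, where segment size controls difficulty). The intended
  breakpoint count is the truth LST by construction and is verified
  against an independent pairwise scan.
- **Counts**: expected per-bin intensity ∝ copy × bin width × a smooth
  GC-bias curve exp(c₁·(gc−0.45) + c₂·(gc−0.45)²) with default
  (c₁, c₂) = (1.5, −3), times a per-bin gamma multiplier with dispersion
  0.05 (negative-binomial marginals, ~22% extra-Poisson CV — a plausible
  bin-level noise for WGA material that passes QC), times occasional
  dropout (rate 0.005, factor 0.3). Reads are allocated multinomially so
  totals are exact. The dispersion/dropout levels were calibrated once so
  that the qualitative depth-titration finding holds: scores stable down
  to ~350K reads, unreliable at ~35K.
- **Genomes**: a 6-chromosome, 1.2-Gb toy genome (1,200 bins) is the test
  default; an hg38-sized genome (3,099 bins) is used where the per-bin
  depth regime matters (depth titration).

What the generator does **not** model: spatially correlated amplification
waves, mappability and assembly-gap artifacts, centromeric noise, doublet
capture, or locus-specific WGA chemistry. Passing the simulation suite
therefore demonstrates the pipeline's statistical behavior under a
realistic noise magnitude, not performance on any particular WGA chemistry.

## Problem sizes in the standard checks

The end-to-end checks run at desk scale: 15-control references; LST
recovery at k ∈ {0, 5, 12, 30} with 20 replicates per k on the toy genome
at 3M reads per cell; depth titration with 10 replicates of a 12-breakpoint
cell on the hg38-sized genome, thinned to 50%, ~11.7% (350K) and ~1.17%
(35K); gene specificity over 400 genes × 20 diploid cells; 500 pure-noise
profiles (n = 50) for split-rate calibration.

## Known limitations

- Per-node alpha of 0.05 across a genome's recursion implies a nonzero
  false-split rate (~1 per 30–40 tested nodes even after validation); LST
  scores of highly rearranged genomes carry a ±1–3 spread from this alone,
  comparable to the replicate score dispersions reported for single-cell
  LST assays of this kind.
- The permutation test assumes within-region exchangeability; fixed per-bin
  effects (reference noise, residual GC structure) violate it mildly.
- Z-score sensitivity is bounded by reference CV (above) and the t₁₄ tail
  floor; the < 1% diploid false-call bound is not attainable with a
  15-cell reference under Gaussian-like noise (expected ≈ 1.2%).
- The residual-over-reads QC metric is one reading of an ambiguous
  published definition and its absolute scale is not comparable to the
  published 1.9 threshold.
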