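"""FISH comparator and concordance statistics.

Scores PTEN/CEP10 FISH signal counts per cell and per patient, then checks
whether a FISH call and a sequencing-based call on the same patient differ
more than sampling would explain, using the two-sided Fisher exact test.
"""

from ctccnv.fish import FishCell, classify_fish_patient
from ctccnv.stats import fisher_exact_2x2

# one patient: 19 evaluable FISH cells, one with a single PTEN signal
cells = [FishCell("c0", 1, 2)] + [FishCell(f"c{i}", 2, 2) for i in range(1, 19)]
call = classify_fish_patient(cells, patient_id="P5")
print(f"FISH patient call: {call.patient_call} "
      f"({call.n_he} HE-loss of {call.n_cells} cells; HE loss needs >= {call.min_he_cells})")

# sequencing on the same patient called 1 of 3 CTCs deleted -> patient-level loss.
# is the FISH (1/19) vs CNV (1/3) difference explicable by sampling?
p = fisher_exact_2x2([[1, 18], [1, 2]])
print(f"Fisher exact p (FISH 1/19 vs CNV 1/3 deleted) = {p:.4f}")
print("\nA p-value this large means the two assays are statistically concordant:")
print("with only 3 sequenced CTCs, a low-prevalence subclone can dominate the call.")
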