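"""PTEN/CEP10 FISH per-cell classification and patient-level scoring.

Per cell: homozygous (HO) loss when PTEN = 0 with CEP10 >= 1, hemizygous
(HE) loss when PTEN = 1 with CEP10 >= 1, non-deleted when PTEN >= 2 with
CEP10 >= 1; a cell without a centromere-10 signal is unevaluable.  Patient
calls require at least 1 HO cell for HO loss or at least 3 HE cells for HE
loss — defaults that reproduce every published patient row; the gain
predicate exists but is off in patient calling because no printed rule
defines it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

HO_LOSS = "HO_loss"
HE_LOSS = "HE_loss"
NON_DELETED = "non_deleted"
GAIN = "gain"
UNEVALUABLE = "unevaluable"


@dataclass
class FishCell:
    cell_id: str
    pten_signals: int
    cep10_signals: int
    cell_class: str = ""

    def __post_init__(self):
        if self.pten_signals < 0 or self.cep10_signals < 0:
            raise ValueError("signal counts must be non-negative")
        if not self.cell_class:
            self.cell_class = classify_fish_cell(self.pten_signals, self.cep10_signals)


@dataclass
class FishPatientCall:
    patient_id: str
    n_cells: int
    n_ho: int
    n_he: int
    n_nd: int
    n_gain: int
    patient_call: str
    min_he_cells: int
    min_ho_cells: int


def classify_fish_cell(
    pten: int,
    cep10: int,
    gain_enabled: bool = False,
    gain_min: int = 4,
) -> str:
    """Classify one cell from its PTEN and CEP10 signal counts."""
    if pten < 0 or cep10 < 0:
        raise ValueError("signal counts must be non-negative")
    if cep10 == 0:
        return UNEVALUABLE
    if pten == 0:
        return HO_LOSS
    if pten == 1:
        return HE_LOSS
    if gain_enabled and pten > cep10 and pten >= gain_min:
        return GAIN
    return NON_DELETED


def classify_fish_patient(
    cells: list[FishCell],
    patient_id: str = "",
    min_he_cells: int = 3,
    min_ho_cells: int = 1,
) -> FishPatientCall:
    """HO loss if enough HO cells, else HE loss if enough HE cells, else non-deleted."""
    evaluable = [c for c in cells if c.cell_class != UNEVALUABLE]
    if not evaluable:
        raise ValueError("no evaluable cells")
    n_ho = sum(c.cell_class == HO_LOSS for c in evaluable)
    n_he = sum(c.cell_class == HE_LOSS for c in evaluable)
    n_nd = sum(c.cell_class == NON_DELETED for c in evaluable)
    n_gain = sum(c.cell_class == GAIN for c in evaluable)
    if n_ho >= min_ho_cells:
        call = HO_LOSS
    elif n_he >= min_he_cells:
        call = HE_LOSS
    else:
        call = NON_DELETED
    return FishPatientCall(
        patient_id=patient_id,
        n_cells=len(evaluable),
        n_ho=n_ho,
        n_he=n_he,
        n_nd=n_nd,
        n_gain=n_gain,
        patient_call=call,
        min_he_cells=min_he_cells,
        min_ho_cells=min_ho_cells,
    )
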