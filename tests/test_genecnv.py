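import numpy as np
import pytest

import ctccnv as cc
from ctccnv.genome import ChromInfo, GeneLocus
from ctccnv.genecnv import GeneZScore, classify_z
from ctccnv.normalize import CellCountProfile


CHROM = ChromInfo("chr10", 130_000_000)


def locus(start, end, name="G", chrom=CHROM.name):
    return GeneLocus(name=name, chrom=chrom, tx_start=start, tx_end=end)


class TestExtendGeneSpan:
    def test_short_gene_extended_symmetrically(self):
        g = cc.extend_gene_span(locus(480_000, 520_000), CHROM)
        assert (g.ext_start, g.ext_end) == (450_000, 550_000)
        assert g.ext_span == 100_000

    def test_long_gene_unchanged(self):
        g = cc.extend_gene_span(locus(1_000_000, 1_150_000), CHROM)
        assert (g.ext_start, g.ext_end) == (1_000_000, 1_150_000)

    def test_left_clamp_shifts_deficit_right(self):
        g = cc.extend_gene_span(locus(10_000, 50_000), CHROM)
        assert g.ext_start == 0
        assert g.ext_span == 100_000

    def test_right_clamp_shifts_deficit_left(self):
        g = cc.extend_gene_span(locus(CHROM.length - 50_000, CHROM.length - 10_000), CHROM)
        assert g.ext_end == CHROM.length
        assert g.ext_span == 100_000

    def test_chromosome_shorter_than_target(self):
        tiny = ChromInfo("chrT", 60_000)
        g = cc.extend_gene_span(locus(10_000, 20_000, chrom="chrT"), tiny)
        assert (g.ext_start, g.ext_end) == (0, 60_000)

    def test_odd_deficit_split(self):
        g = cc.extend_gene_span(locus(500_000, 500_001), CHROM)
        assert g.ext_span == 100_000
        assert g.ext_start <= 500_000 < g.ext_end


class TestZScore:
    def test_zero_at_reference_mean(self):
        assert cc.z_score(10.0, 10.0, 2.0) == 0.0

    def test_cutoffs_are_strict(self):
        assert classify_z(3.0) == "neutral"
        assert classify_z(3.0001) == "amplified"
        assert classify_z(-3.0) == "neutral"
        assert classify_z(-3.0001) == "deleted"

    def test_zero_sd_unevaluable_not_infinite(self):
        z = cc.z_score(5.0, 1.0, 0.0)
        assert np.isnan(z)
        assert classify_z(z) == "unevaluable"

    def test_affine_equivariance(self, rng):
        x, m, s = 13.0, 10.0, 2.0
        base = cc.z_score(x, m, s)
        assert cc.z_score(x + 7, m + 7, s) == pytest.approx(base)
        assert cc.z_score(3 * x, 3 * m, 3 * s) == pytest.approx(base)


class TestCallCellGenes:
    def _setup(self, rng, n_genes=60, truth_copy=None):
        genome = [ChromInfo("chr1", 200_000_000)]
        genes = cc.simulate_gene_table(genome, n_genes, seed=5)
        genes = [cc.extend_gene_span(g, genome[0]) for g in genes]
        gc = np.clip(rng.normal(0.45, 0.05, n_genes), 0.3, 0.6)
        spans = np.array([g.ext_span for g in genes], dtype=float)
        lam = spans / spans.mean() * 800
        controls = []
        for i in range(15):
            counts = rng.poisson(lam)
            controls.append(cc.normalize_cell(
                CellCountProfile(f"w{i}", counts, "raw"), gc=gc))
        ref = cc.mask_low_coverage(cc.build_reference(controls), 10)
        mult = np.ones(n_genes) if truth_copy is None else truth_copy / 2.0
        cell = cc.normalize_cell(
            CellCountProfile("t", rng.poisson(lam * mult), "raw"), gc=gc)
        return cell, ref, genes

    def test_homozygous_deletion_called(self, rng):
        copy = np.full(60, 2.0)
        copy[7] = 0.0
        cell, ref, genes = self._setup(rng, truth_copy=copy)
        calls = cc.call_cell_genes(cell, ref, genes)
        assert calls[7].call == "deleted"

    def test_high_amplification_called(self, rng):
        copy = np.full(60, 2.0)
        copy[11] = 8.0
        cell, ref, genes = self._setup(rng, truth_copy=copy)
        calls = cc.call_cell_genes(cell, ref, genes)
        assert calls[11].call == "amplified"

    def test_masked_gene_unevaluable(self, rng):
        cell, ref, genes = self._setup(rng)
        ref.mask[3] = False
        calls = cc.call_cell_genes(cell, ref, genes)
        assert calls[3].call == "unevaluable"
        assert np.isnan(calls[3].z)

    def test_monotone_in_x(self):
        # increasing X can never move a call from amplified toward deleted
        order = {"deleted": 0, "neutral": 1, "amplified": 2}
        prev = 0
        for x in np.linspace(0, 40, 30):
            call = classify_z(cc.z_score(x, 20.0, 2.0))
            assert order[call] >= prev
            prev = order[call]


def zs(cell_id, call, gene="PTEN"):
    z = {"amplified": 4.0, "deleted": -4.0, "neutral": 0.0}[call]
    return GeneZScore(cell_id, gene, 0.0, 0.0, 1.0, z, 0.0, call)


class TestCallPatient:
    def test_two_cell_rule(self):
        cells = [zs(f"c{i}", "deleted") for i in range(5)] + \
                [zs(f"n{i}", "neutral") for i in range(10)]
        assert cc.call_patient(cells, min_cells=2).patient_call == "deleted"

    def test_published_per_patient_counts_at_min_cells_one(self):
        # printed per-patient deleted/evaluated counts -> loss in 5 of 7
        counts = {"1": (5, 9), "2": (3, 16), "3": (0, 17), "4": (0, 2),
                  "5": (1, 3), "6": (1, 5), "7": (5, 15)}
        called = set()
        for pid, (ndel, nev) in counts.items():
            cells = [zs(f"{pid}.{i}", "deleted" if i < ndel else "neutral")
                     for i in range(nev)]
            if cc.call_patient(cells, min_cells=1).patient_call == "deleted":
                called.add(pid)
        assert called == {"1", "2", "5", "6", "7"}

    def test_min_cells_one_at_least_as_sensitive(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 12))
            calls = [zs(f"c{i}", rng.choice(["deleted", "neutral", "amplified"]))
                     for i in range(n)]
            loose = cc.call_patient(calls, min_cells=1).patient_call
            strict = cc.call_patient(calls, min_cells=2).patient_call
            if strict != "none":
                assert loose != "none"

    def test_zero_altered_cells_none(self):
        assert cc.call_patient([zs("c", "neutral")]).patient_call == "none"

    def test_discordant_directions_flagged(self):
        cells = [zs(f"a{i}", "amplified") for i in range(3)] + \
                [zs(f"d{i}", "deleted") for i in range(2)]
        call = cc.call_patient(cells, min_cells=2)
        assert call.patient_call == "amplified"
        assert any("discordant" in f for f in call.flags)

    def test_no_evaluable_cells_is_an_error(self):
        unev = GeneZScore("c", "G", 0, 0, 0, float("nan"), float("nan"), "unevaluable")
        with pytest.raises(ValueError, match="evaluable"):
            cc.call_patient([unev])
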