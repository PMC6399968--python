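import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import embryonet as en
from embryonet.barcodes import (
    MixtureFit,
    chi_square_2x2,
    call_barcode,
    fit_mixture,
    group_cells_by_panel,
    panel_profile,
    posterior_expressed,
    process_qpcr,
)
from embryonet.io import GenePanel


def _matrix(values, cells=None):
    values = pd.DataFrame(values)
    values.index = [f"G{i}" for i in range(len(values))]
    values.columns = cells or [f"c{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame({"stage": ["8cell"] * values.shape[1]},
                        index=values.columns)
    return en.ExpressionMatrix(values, meta)


class TestMixtureCaller:
    def test_two_well_separated_components_called_accurately(self):
        rng = np.random.default_rng(0)
        n_genes, n_cells = 200, 10
        truth = rng.random((n_genes, n_cells)) < 0.5
        vals = np.where(truth, rng.normal(8, 1, (n_genes, n_cells)),
                        rng.normal(4, 1, (n_genes, n_cells)))
        barcode = call_barcode(_matrix(vals))
        acc = (barcode.calls.to_numpy() == truth).mean()
        assert acc >= 0.95

    def test_midpoint_posterior_is_half_and_called_present(self):
        fit = MixtureFit(4.0, 1.0, 8.0, 1.0, 0.5)
        post = posterior_expressed(np.array([6.0]), fit)
        assert post[0] == pytest.approx(0.5)
        assert post[0] >= 0.5  # the >= rule calls the boundary present

    def test_housekeeping_gene_present_everywhere(self):
        rng = np.random.default_rng(1)
        vals = np.vstack([rng.normal(8, 0.5, 8),
                          rng.normal(4, 0.5, 8),
                          rng.normal(6, 2.0, 8)])
        vals = np.vstack([vals, rng.normal(4, 1, (30, 8)),
                          rng.normal(8, 1, (30, 8))])
        barcode = call_barcode(_matrix(vals))
        assert barcode.calls.loc["G0"].sum() == 8
        assert barcode.calls.loc["G1"].sum() == 0

    def test_calls_invariant_under_global_shift(self):
        rng = np.random.default_rng(2)
        truth = rng.random((80, 8)) < 0.5
        vals = np.where(truth, rng.normal(8, 1, (80, 8)), rng.normal(4, 1, (80, 8)))
        a = call_barcode(_matrix(vals)).calls
        b = call_barcode(_matrix(vals + 3.5)).calls
        pd.testing.assert_frame_equal(a, b)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            call_barcode(_matrix(np.full((5, 4), 2.0)))

    def test_quartile_init_makes_fit_shift_equivariant(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(4, 1, 200), rng.normal(9, 1, 200)])
        f1 = fit_mixture(x)
        f2 = fit_mixture(x + 10.0)
        assert f2.mean_unexpressed - f1.mean_unexpressed == pytest.approx(10, abs=1e-6)
        assert f2.midpoint - f1.midpoint == pytest.approx(10, abs=1e-6)


class TestVariableFilter:
    def _barcode(self, counts, n_cells=8):
        calls = pd.DataFrame(
            [[1] * c + [0] * (n_cells - c) for c in counts],
            index=[f"G{i}" for i in range(len(counts))],
            columns=[f"B{i+1}" for i in range(n_cells)])
        return en.PresenceMatrix(calls, provenance="barcode")

    def test_two_to_five_of_eight_rule(self):
        barcode = self._barcode([0, 1, 2, 3, 5, 6, 8])
        kept = en.blastomere_variable_filter(barcode)
        assert kept == {"G2", "G3", "G4"}

    def test_full_range_keeps_everything(self):
        barcode = self._barcode([0, 1, 4, 8])
        kept = en.blastomere_variable_filter(barcode, min_cells=0, max_cells=8)
        assert len(kept) == 4


class TestPanels:
    def test_counts_recover_graded_truth(self):
        genes = [f"P{i}" for i in range(10)]
        calls = pd.DataFrame({"A": [1] * 10, "B": [1] * 3 + [0] * 7}, index=genes)
        panel = GenePanel("EIF", frozenset(genes))
        views = panel_profile(calls, [panel])
        counts = views["EIF"].loc["count"]
        assert counts["A"] == 10 and counts["B"] == 3

    def test_unmeasured_panel_skipped(self):
        calls = pd.DataFrame({"A": [1]}, index=["G0"])
        views = panel_profile(calls, [GenePanel("missing", frozenset({"ZZZ"}))])
        assert views == {}

    def test_identical_cells_grouped_together(self):
        calls = pd.DataFrame({"A": [1, 1, 0], "B": [1, 1, 0], "C": [0, 0, 1]},
                             index=["G0", "G1", "G2"])
        groups = group_cells_by_panel(calls, k=2)
        assert groups["A"] == groups["B"] != groups["C"]

    def test_k_equal_cells_gives_singletons(self):
        calls = pd.DataFrame({"A": [1, 0], "B": [0, 1], "C": [1, 1]},
                             index=["G0", "G1"])
        groups = group_cells_by_panel(calls, k=3)
        assert len(set(groups.values())) == 3

    def test_planted_two_group_recovery(self, planted_study):
        truth = planted_study["truth"]
        barcode = planted_study["barcode"].calls
        from embryonet.synthetic import blastomere_panels, EPI_PANEL
        panel = next(p for p in blastomere_panels(planted_study["config"])
                     if p.name == EPI_PANEL)
        groups = group_cells_by_panel(barcode, panel, k=2)
        by_truth = {}
        for cell, grp in groups.items():
            by_truth.setdefault(truth.blastomere_groups[cell], set()).add(grp)
        assert all(len(v) == 1 for v in by_truth.values())
        assert by_truth["ICM-like"] != by_truth["TE-like"]


def chi2_formula(table):
    """Oracle: direct Pearson formula sum (O-E)^2/E."""
    table = np.asarray(table, float)
    n = table.sum()
    expected = np.outer(table.sum(1), table.sum(0)) / n
    return ((table - expected) ** 2 / expected).sum()


class TestQPCR:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["cell", "gene", "ct_rep1", "ct_rep2",
                                           "ct_rep3"])

    def test_delta_ct_is_forty_minus_ct(self):
        t = self._table([["c1", "GATA3", 30.0, 30.0, 30.0]])
        res = process_qpcr(t, min_expressed_genes=1)
        assert res.delta_ct.loc["c1", "GATA3"] == pytest.approx(10.0)

    def test_thirtyseven_cycle_detection_boundary(self):
        t = self._table([["c1", "A", 37.0, 37.0, 37.0],
                         ["c1", "B", 38.0, 38.0, 38.0]])
        res = process_qpcr(t, min_expressed_genes=0)
        assert bool(res.expressed.loc["c1", "A"])
        assert not bool(res.expressed.loc["c1", "B"])

    def test_inclusion_needs_more_than_three_genes(self):
        rows = [["c1", f"G{i}", 30.0, 30.0, 30.0] for i in range(4)]
        rows += [["c2", f"G{i}", 30.0, 30.0, 30.0] for i in range(3)]
        rows += [["c2", "G3", 39.0, 39.0, 39.0]]
        res = process_qpcr(self._table(rows))
        assert res.included_cells == ["c1"]
        assert res.excluded_cells == ["c2"]

    def test_perfectly_associated_genes_significant(self):
        stat, p = chi_square_2x2([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert p < 0.05

    @pytest.mark.parametrize("seed", range(6))
    def test_chi_square_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 13, size=(2, 2))
        stat, p = chi_square_2x2(table)
        assert stat == pytest.approx(chi2_formula(table), abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(stat, 1), abs=1e-12)

    def test_degenerate_margin_is_uninformative(self):
        stat, p = chi_square_2x2([[5, 5], [0, 0]])
        assert (stat, p) == (0.0, 1.0)

    def test_majority_replicate_rule(self):
        t = self._table([["c1", "A", 36.0, 36.5, 39.0]])
        mean_res = process_qpcr(t, min_expressed_genes=0, replicate_rule="mean")
        maj_res = process_qpcr(t, min_expressed_genes=0, replicate_rule="majority")
        assert not bool(mean_res.expressed.loc["c1", "A"])  # mean 37.17 > 37
        assert bool(maj_res.expressed.loc["c1", "A"])  # 2 of 3 <= 37
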