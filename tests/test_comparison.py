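import itertools
import math

import numpy as np
import pandas as pd
import pytest

import embryonet as en
from embryonet.comparison import (
    OverlapTable,
    RegulonDB,
    causal_zscore,
    export_circos,
    hypergeom_upper_tail,
    hypergeometric_enrichment,
    module_similarity,
    track_modules,
)
from embryonet.io import GenePanel
from embryonet.modules import Module, ModuleSet
from embryonet.stage_stats import StageDEResult


def make_moduleset(entity, member_lists):
    modules = []
    for i, members in enumerate(member_lists):
        members = frozenset(members)
        modules.append(Module(metanode=sorted(members)[0], members=members,
                              membership={m: 1.0 for m in members},
                              centrality_score=float(len(member_lists) - i),
                              top_members=sorted(members)))
    return ModuleSet(modules, entity=entity)


def hypergeom_enumeration(population, successes, draws, observed):
    """Oracle: enumerate every possible draw of ``draws`` items."""
    items = list(range(population))
    marked = set(range(successes))
    hits = total = 0
    for combo in itertools.combinations(items, draws):
        total += 1
        if len(marked & set(combo)) >= observed:
            hits += 1
    return hits / total


class TestTrackModules:
    def test_identical_modulesets_link_to_themselves(self):
        a = make_moduleset("s1", [list("ABCDE"), list("FGHIJ")])
        b = make_moduleset("s2", [list("ABCDE"), list("FGHIJ")])
        links, flags = track_modules([a, b])
        self_links = links[links["moduleA"] == links["moduleB"]]
        assert len(self_links) == 2
        assert set(self_links["shared_genes"]) == {5}
        assert not flags["no_shared_elements"].any()

    def test_disjoint_modules_all_flagged(self):
        a = make_moduleset("s1", [list("ABC")])
        b = make_moduleset("s2", [list("XYZ")])
        links, flags = track_modules([a, b])
        assert links.empty
        assert flags["no_shared_elements"].all()

    def test_threshold_is_more_than_two_shared(self):
        a = make_moduleset("s1", [list("ABCDE"), list("VWXYZ")])
        b = make_moduleset("s2", [list("ABCQR"), list("VWQRS")])
        links, _ = track_modules([a, b])  # shares 3 and 2 respectively
        assert len(links) == 1
        assert links.iloc[0]["shared_genes"] == 3


class TestModuleSimilarity:
    universe = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")

    def test_five_shared_is_similar_four_is_not(self):
        a = make_moduleset("B1", [list("ABCDEF")])
        b5 = make_moduleset("B2", [list("ABCDEZ")])
        b4 = make_moduleset("B3", [list("ABCDYZ")])
        assert module_similarity(a, b5, self.universe).pairs["similar"].all()
        assert not module_similarity(a, b4, self.universe).pairs["similar"].any()

    def test_saturated_overlap_has_p_one(self):
        universe = set("ABCDE")
        a = make_moduleset("x", [list("ABCDE")])
        b = make_moduleset("y", [list("ABCDE")])
        table = module_similarity(a, b, universe)
        assert table.pairs["p_value"].iloc[0] == pytest.approx(1.0)

    def test_small_universe_raises(self):
        a = make_moduleset("x", [list("ABCDEF")])
        with pytest.raises(ValueError):
            module_similarity(a, a, set("ABC"))

    def test_symmetry_under_entity_swap(self):
        a = make_moduleset("x", [list("ABCDE"), list("FGHIJ")])
        b = make_moduleset("y", [list("ABCFG"), list("KLMNO")])
        t_ab = module_similarity(a, b, self.universe).pairs
        t_ba = module_similarity(b, a, self.universe).pairs
        key_ab = {(r.moduleA, r.moduleB): (r.shared_genes, r.p_value)
                  for r in t_ab.itertuples()}
        key_ba = {(r.moduleB, r.moduleA): (r.shared_genes, r.p_value)
                  for r in t_ba.itertuples()}
        assert key_ab == key_ba


class TestHypergeometric:
    def test_five_of_five_from_half_marked_population(self):
        # all 5 draws marked out of 5 marked in 10: p = 1/C(10,5) = 1/252
        p = hypergeom_upper_tail(10, 5, 5, 5)
        assert p == pytest.approx(1 / 252)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        population = int(rng.integers(4, 13))
        successes = int(rng.integers(1, population + 1))
        draws = int(rng.integers(1, population + 1))
        observed = int(rng.integers(0, min(successes, draws) + 1))
        assert hypergeom_upper_tail(population, successes, draws, observed) == \
            pytest.approx(hypergeom_enumeration(population, successes, draws,
                                                observed), abs=1e-12)

    def test_enrichment_fold_and_certainty(self):
        universe = {f"G{i}" for i in range(20)}
        panel = GenePanel("p", frozenset(list(universe)[:10]))
        hits = set(list(panel.members)[:5]) | set(sorted(universe - panel.members)[:5])
        p, fold = hypergeometric_enrichment(hits, panel, universe)
        assert fold == pytest.approx(1.0)  # observed 5 == expected 10*10/20
        full_panel = GenePanel("u", frozenset(universe))
        p_full, _ = hypergeometric_enrichment(hits, full_panel, universe)
        assert p_full == pytest.approx(1.0)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment({"A"}, GenePanel("p", frozenset({"Z"})),
                                      {"A", "B"})


def _de_result(changes, de_genes):
    table = pd.DataFrame({
        "F": 10.0, "p": 0.001, "q": 0.001,
        "mean_first": 0.0, "mean_last": pd.Series(changes),
        "degenerate": False,
    })
    table["q"] = [0.01 if g in de_genes else 0.5 for g in table.index]
    return StageDEResult(table)


class TestCausalZScore:
    def _db(self, regulator, signs):
        return RegulonDB(pd.DataFrame({
            "regulator": regulator,
            "target": [f"T{i}" for i in range(len(signs))],
            "sign": signs,
        }))

    def test_five_consistent_targets_flagged(self):
        changes = pd.Series({f"T{i}": 1.0 for i in range(5)})
        res = causal_zscore(_de_result(changes, set(changes.index)),
                            self._db("R", [1] * 5))
        assert res.iloc[0]["z"] == pytest.approx(5 / math.sqrt(5))
        assert bool(res.iloc[0]["flagged"])

    def test_balanced_targets_score_zero(self):
        changes = pd.Series({f"T{i}": 1.0 for i in range(4)})
        res = causal_zscore(_de_result(changes, set(changes.index)),
                            self._db("R", [1, 1, -1, -1]))
        assert res.iloc[0]["z"] == pytest.approx(0.0)

    def test_z_exactly_two_is_not_flagged(self):
        changes = pd.Series({f"T{i}": 1.0 for i in range(4)})
        res = causal_zscore(_de_result(changes, set(changes.index)),
                            self._db("R", [1] * 4))
        assert res.iloc[0]["z"] == pytest.approx(2.0)
        assert not bool(res.iloc[0]["flagged"])

    def test_sign_flip_negates_z(self):
        changes = pd.Series({f"T{i}": 1.0 for i in range(5)})
        de = _de_result(changes, set(changes.index))
        plus = causal_zscore(de, self._db("R", [1, 1, 1, 1, -1]))
        minus = causal_zscore(de, self._db("R", [-1, -1, -1, -1, 1]))
        assert plus.iloc[0]["z"] == pytest.approx(-minus.iloc[0]["z"])


class TestCircosExport:
    def _table(self, rows):
        pairs = pd.DataFrame(rows, columns=["entityA", "moduleA", "entityB",
                                            "moduleB", "shared_genes",
                                            "shared_list", "p_value", "similar",
                                            "q_value"])
        return OverlapTable(pairs, min_shared=5, universe_size=100)

    def test_empty_table_writes_headers_only(self, tmp_path):
        table = self._table([])
        export_circos(table, tmp_path / "links.txt")
        lines = (tmp_path / "links.txt").read_text().splitlines()
        assert all(line.startswith("#") for line in lines)

    def test_entity_order_is_canonical(self, tmp_path):
        rows_fwd = [["B1", "m1", "B2", "n1", 6, "", 0.01, True, 0.01]]
        rows_rev = [["B2", "n1", "B1", "m1", 6, "", 0.01, True, 0.01]]
        export_circos(self._table(rows_fwd), tmp_path / "a.txt")
        export_circos(self._table(rows_rev), tmp_path / "b.txt")
        a = (tmp_path / "a.txt").read_text().splitlines()[1]
        b = (tmp_path / "b.txt").read_text().splitlines()[1]
        assert a.split()[:2] == b.split()[:2] == ["B1", "B2"]

    def test_counts_sorted_descending(self, tmp_path):
        rows = ([["B1", f"m{i}", "B2", f"n{i}", 6, "", 0.01, True, 0.01]
                 for i in range(3)] +
                [["B3", f"m{i}", "B4", f"n{i}", 6, "", 0.01, True, 0.01]
                 for i in range(7)])
        export_circos(self._table(rows), tmp_path / "links.txt")
        lines = [l for l in (tmp_path / "links.txt").read_text().splitlines()
                 if not l.startswith("#")]
        counts = [int(l.split()[2]) for l in lines[:2]]
        assert counts == [7, 3]
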