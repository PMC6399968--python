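"""Cross-network module comparison: stage-to-stage module tracking, pairwise
module similarity between cells/tissues with hypergeometric significance,
circos link export, panel enrichment, and signed-regulon causal z-scores.

Thresholds follow the study's stated rules: modules are tracked across
consecutive stages when they share more than 2 members (i.e. >= 3), module
pairs between cells count as "similar" when they share >= 5 genes, and an
upstream regulator is flagged when |z| exceeds 2 strictly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenePanel
from .modules import ModuleSet
from .stage_stats import StageDEResult, bh_qvalues

log = logging.getLogger(__name__)


@dataclass
class OverlapTable:
    pairs: pd.DataFrame  # entityA,moduleA,entityB,moduleB,shared_genes,shared_list,p_value,q_value,similar
    min_shared: int
    universe_size: int

    def similar_counts(self) -> pd.DataFrame:
        """Per entity pair, the number of similar module pairs (circos input)."""
        sim = self.pairs[self.pairs["similar"].astype(bool)]
        counts = (sim.groupby(["entityA", "entityB"]).size()
                  .reset_index(name="count"))
        return counts.sort_values(["count", "entityA", "entityB"],
                                  ascending=[False, True, True], ignore_index=True)

    def entity_totals(self) -> pd.Series:
        counts = self.similar_counts()
        totals: dict[str, int] = {}
        for _, row in counts.iterrows():
            totals[row["entityA"]] = totals.get(row["entityA"], 0) + row["count"]
            totals[row["entityB"]] = totals.get(row["entityB"], 0) + row["count"]
        return pd.Series(totals, dtype=int).sort_index()


@dataclass
class RegulonDB:
    edges: pd.DataFrame  # regulator, target, sign (+1/-1)

    def __post_init__(self) -> None:
        if self.edges.duplicated(["regulator", "target"]).any():
            raise ValueError("duplicate (regulator, target) pairs in regulon DB")
        if not set(self.edges["sign"]).issubset({1, -1}):
            raise ValueError("regulon signs must be +1/-1")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegulonDB":
        df = pd.read_csv(path, sep="\t", names=["regulator", "target", "sign"],
                         header=0 if "regulator" in open(path).readline() else None)
        return cls(df.assign(sign=df["sign"].astype(int)))


def hypergeom_upper_tail(population: int, successes: int, draws: int, observed: int) -> float:
    """P[X >= observed] for a hypergeometric draw."""
    if not (0 <= successes <= population and 0 <= draws <= population):
        raise ValueError("invalid hypergeometric parameters")
    return float(stats.hypergeom.sf(observed - 1, population, successes, draws))


def track_modules(stage_module_sets: list[ModuleSet], min_shared: int = 3
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Links between modules of consecutive stages sharing >= min_shared genes.

    Returns (links, flags): ``links`` has one row per qualifying module pair
    with the shared count as weight; ``flags`` marks modules with no link to
    either the preceding or following stage.
    """
    if len(stage_module_sets) < 2:
        raise ValueError("need at least 2 stages to track modules")
    links = []
    linked: set[tuple[int, int]] = set()
    for i, (cur, nxt) in enumerate(zip(stage_module_sets, stage_module_sets[1:])):
        for mi, m in enumerate(cur.modules):
            for ni, n in enumerate(nxt.modules):
                shared = m.members & n.members
                if len(shared) >= min_shared:
                    links.append({
                        "stageA": cur.entity or str(i), "moduleA": m.metanode,
                        "stageB": nxt.entity or str(i + 1), "moduleB": n.metanode,
                        "shared_genes": len(shared),
                        "shared_list": ";".join(sorted(shared)),
                    })
                    linked.add((i, mi))
                    linked.add((i + 1, ni))
    flags = []
    for i, mset in enumerate(stage_module_sets):
        for mi, m in enumerate(mset.modules):
            flags.append({"stage": mset.entity or str(i), "metanode": m.metanode,
                          "no_shared_elements": (i, mi) not in linked})
    link_df = pd.DataFrame(links, columns=["stageA", "moduleA", "stageB", "moduleB",
                                           "shared_genes", "shared_list"])
    return link_df, pd.DataFrame(flags)


def module_similarity(msetA: ModuleSet, msetB: ModuleSet, universe: set,
                      min_shared: int = 5) -> OverlapTable:
    """All-pairs module overlap between two entities with hypergeometric p.

    For modules a (size K) and b (size n) over a universe of N genes, the
    p-value is the upper tail of Hypergeom(N, K, n) at the observed shared
    count.  Pairs sharing >= min_shared genes are "similar".  BH q-values
    are computed within the entity pair.
    """
    universe = set(universe)
    for mset in (msetA, msetB):
        for m in mset.modules:
            if not m.members <= universe:
                raise ValueError("universe must contain every module member")
    n_pop = len(universe)
    rows = []
    for a in msetA.modules:
        for b in msetB.modules:
            shared = a.members & b.members
            p = hypergeom_upper_tail(n_pop, len(a.members), len(b.members), len(shared))
            rows.append({
                "entityA": msetA.entity, "moduleA": a.metanode,
                "entityB": msetB.entity, "moduleB": b.metanode,
                "shared_genes": len(shared),
                "shared_list": ";".join(sorted(shared)),
                "p_value": p,
                "similar": len(shared) >= min_shared,
            })
    pairs = pd.DataFrame(rows)
    pairs["q_value"] = bh_qvalues(pairs["p_value"].to_numpy()) if len(pairs) else []
    return OverlapTable(pairs, min_shared, n_pop)


def similarity_matrix(module_sets: list[ModuleSet], universe: set,
                      min_shared: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise similar-module counts across many entities.

    Returns (counts matrix entity x entity, long-form pair table).
    """
    names = [m.entity for m in module_sets]
    counts = pd.DataFrame(0, index=names, columns=names)
    all_pairs = []
    for i, a in enumerate(module_sets):
        for b in module_sets[i + 1:]:
            tab = module_similarity(a, b, universe, min_shared=min_shared)
            n_sim = int(tab.pairs["similar"].sum())
            counts.loc[a.entity, b.entity] = n_sim
            counts.loc[b.entity, a.entity] = n_sim
            all_pairs.append(tab.pairs)
    pair_table = pd.concat(all_pairs, ignore_index=True) if all_pairs else pd.DataFrame()
    return counts, pair_table


def hypergeometric_enrichment(hit_set: set, panel: GenePanel, universe: set
                              ) -> tuple[float, float]:
    """Upper-tail enrichment of a hit set for a panel over a gene universe.

    Returns (p_value, fold) with fold = observed / expected overlap.
    """
    universe = set(universe)
    hits = set(hit_set) & universe
    members = set(panel.members) & universe
    if not members:
        raise ValueError(f"panel {panel.name!r} has no genes in the universe")
    observed = len(hits & members)
    expected = len(hits) * len(members) / len(universe) if universe else 0.0
    p = hypergeom_upper_tail(len(universe), len(members), len(hits), observed)
    fold = observed / expected if expected > 0 else float("inf")
    return p, fold


def causal_zscore(de_result: StageDEResult, regulons: RegulonDB,
                  log_change: pd.Series | None = None, z_threshold: float = 2.0
                  ) -> pd.DataFrame:
    """Signed-consistency z-score per upstream regulator.

    For a regulator with n scored targets, z = (n_consistent − n_inconsistent)
    / sqrt(n), where a target is consistent when the regulon edge sign and the
    observed direction of change agree.  Direction of change defaults to the
    difference between the last and first per-stage means in the DE table.
    Regulators are flagged at |z| strictly greater than ``z_threshold``.
    """
    table = de_result.table
    if log_change is None:
        mean_cols = [c for c in table.columns if c.startswith("mean_")]
        if len(mean_cols) < 2:
            raise ValueError("DE table lacks per-stage means to derive a direction")
        log_change = table[mean_cols[-1]] - table[mean_cols[0]]
    de_genes = de_result.de_genes
    rows = []
    for regulator, sub in regulons.edges.groupby("regulator", sort=True):
        n_cons = n_incons = 0
        for _, edge in sub.iterrows():
            target = edge["target"]
            if target not in de_genes or target not in log_change.index:
                continue
            direction = np.sign(log_change[target])
            if direction == 0:
                continue
            if edge["sign"] * direction > 0:
                n_cons += 1
            else:
                n_incons += 1
        n = n_cons + n_incons
        if n == 0:
            log.info("causal_zscore: regulator %s has no scored targets", regulator)
            continue
        z = (n_cons - n_incons) / np.sqrt(n)
        rows.append({"regulator": regulator, "n": n, "z": float(z),
                     "flagged": bool(abs(z) > z_threshold)})
    return pd.DataFrame(rows, columns=["regulator", "n", "z", "flagged"])


def export_circos(table: OverlapTable, path: str | Path) -> None:
    """Write circos-style link files: per-entity-pair similar-module counts
    (sorted by count descending, then canonical entity order) followed by the
    detailed similar module pairs."""
    counts = table.similar_counts()
    canon = counts.copy()
    swap = canon["entityA"] > canon["entityB"]
    canon.loc[swap, ["entityA", "entityB"]] = canon.loc[swap, ["entityB", "entityA"]].to_numpy()
    canon = canon.sort_values(["count", "entityA", "entityB"],
                              ascending=[False, True, True], ignore_index=True)
    with open(path, "w") as fh:
        fh.write("# entityA entityB similar_module_count\n")
        for _, row in canon.iterrows():
            fh.write(f"{row['entityA']} {row['entityB']} {row['count']}\n")
        fh.write("# entityA moduleA entityB moduleB shared_genes\n")
        sim = table.pairs[table.pairs["similar"].astype(bool)].sort_values(
            ["shared_genes", "entityA", "entityB", "moduleA", "moduleB"],
            ascending=[False, True, True, True, True])
        for _, row in sim.iterrows():
            fh.write(f"{row['entityA']} {row['moduleA']} {row['entityB']} "
                     f"{row['moduleB']} {row['shared_genes']}\n")
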