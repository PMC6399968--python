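"""Background interactome handling and stage/blastomere network inference.

A stage network is built from a seed set (e.g. the stage's differentially
expressed or barcode-present genes) by adding a minimal number of connecting
proteins from the background interactome until the seeds form one connected
model.  "Minimal" is realised as a greedy shortest-path Steiner approximation;
the exact optimum is intractable in general but the greedy result is bounded
and audited by tests on small instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, normalize_symbol

log = logging.getLogger(__name__)


@dataclass
class SeedSet:
    genes: frozenset
    direction: dict = field(default_factory=dict)  # gene -> up|down|none

    def __post_init__(self) -> None:
        self.genes = frozenset(normalize_symbol(g) for g in self.genes)
        self.direction = {normalize_symbol(g): d for g, d in self.direction.items()}
        extra = set(self.direction) - set(self.genes)
        if extra:
            raise ValueError(f"directions for genes outside the seed set: {sorted(extra)}")


@dataclass
class NetworkModel:
    graph: nx.Graph
    node_role: dict  # gene -> seed|connector
    stage: str = ""
    unreachable_seeds: frozenset = frozenset()

    @property
    def seeds(self) -> set:
        return {n for n, r in self.node_role.items() if r == "seed"}

    @property
    def connectors(self) -> set:
        return {n for n, r in self.node_role.items() if r == "connector"}


def load_interactome(path: str | Path, fmt: str = "simple",
                     symbol_columns: tuple[int, int] = (7, 8)) -> nx.Graph:
    """Load an undirected interactome from a tab-delimited edge list.

    ``fmt='simple'`` expects two symbol columns; ``fmt='tab2-like'`` takes the
    official-symbol columns of a BioGRID-style file (0-based indices in
    ``symbol_columns``).  Symbols are uppercased; duplicates and self-loops
    are dropped.
    """
    cols = (0, 1) if fmt == "simple" else tuple(symbol_columns)
    g = nx.Graph()
    n_rows = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if max(cols) >= len(parts):
                continue
            a, b = normalize_symbol(parts[cols[0]]), normalize_symbol(parts[cols[1]])
            if line_no == 0 and fmt == "simple" and a in ("GENEA", "GENE_A", "SOURCE"):
                continue
            n_rows += 1
            if a == b:
                continue
            g.add_edge(a, b)
    if g.number_of_edges() == 0:
        raise ValueError(f"no edges parsed from {path}")
    log.info("interactome: %d rows -> %d nodes, %d edges", n_rows,
             g.number_of_nodes(), g.number_of_edges())
    return g


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


def _path_tiebreak(graph: nx.Graph, path: list, included: set) -> tuple:
    """Prefer fewer new nodes, then higher total degree, then lexicographic."""
    new_nodes = [n for n in path if n not in included]
    return (len(new_nodes), -sum(graph.degree(n) for n in new_nodes), tuple(path))


def infer_network(interactome: nx.Graph, seeds: SeedSet,
                  max_connector_path: int = 2, stage: str = "") -> NetworkModel:
    """Greedy minimal-connector subnetwork over a seed gene set.

    Starting from the largest seed-induced connected component, repeatedly
    merge the nearest remaining seed component via a shortest interactome
    path of at most ``max_connector_path`` edges, adding path-interior nodes
    as connectors; finally all interactome edges among included nodes are
    added.  Seeds not reachable within the limit are reported (and kept as
    isolated nodes).  Seeds missing from the interactome entirely raise if
    none remain.
    """
    present = sorted(seeds.genes & set(interactome.nodes))
    missing = seeds.genes - set(interactome.nodes)
    if missing:
        log.warning("infer_network: %d seeds absent from interactome", len(missing))
    if len(present) == 0:
        raise ValueError("no seeds present in the interactome")

    induced = interactome.subgraph(present)
    comps = sorted(nx.connected_components(induced),
                   key=lambda c: (-len(c), min(c)))
    included: set = set(comps[0])
    remaining = [set(c) for c in comps[1:]]
    unreachable: set = set()

    aux_source = object()  # placeholder super-source, never a gene symbol
    while remaining:
        lengths = nx.multi_source_dijkstra_path_length(
            interactome, included, cutoff=max_connector_path)
        candidates = [(lengths[n], ci, n) for ci, comp in enumerate(remaining)
                      for n in comp if n in lengths]
        if not candidates:
            for comp in remaining:
                unreachable |= comp
            break
        dmin = min(c[0] for c in candidates)
        aux = nx.Graph(interactome)
        aux.add_edges_from((aux_source, n) for n in included)
        best = None  # (tiebreak_key, comp_index, path)
        for dist, ci, target in candidates:
            if dist != dmin:
                continue
            # consider every shortest path from the model to this seed
            for aux_path in nx.all_shortest_paths(aux, aux_source, target):
                path = aux_path[1:]
                key = _path_tiebreak(interactome, path, included)
                if best is None or (key, ci) < (best[0], best[1]):
                    best = (key, ci, path)
        _, ci, path = best
        included |= set(path) | remaining[ci]
        remaining.pop(ci)

    nodes = included | unreachable
    sub = nx.Graph()
    sub.add_nodes_from(sorted(nodes))
    sub.add_edges_from((a, b) for a, b in interactome.subgraph(nodes).edges)
    roles = {n: ("seed" if n in seeds.genes else "connector") for n in sub.nodes}
    nx.set_node_attributes(sub, roles, "role")
    return NetworkModel(sub, roles, stage=stage, unreachable_seeds=frozenset(unreachable))


def coexpression_network(matrix: ExpressionMatrix, r_threshold: float = 0.9) -> nx.Graph:
    """Absolute-correlation co-expression graph (|r| >= threshold).

    Constant genes have no defined correlation and are excluded (logged).
    Used as a robustness cross-check against interactome-derived modules.
    """
    if len(matrix.samples) < 4:
        raise ValueError("need at least 4 samples for co-expression")
    vals = matrix.values.to_numpy(float)
    sd = vals.std(axis=1)
    keep = sd > 0
    n_const = int((~keep).sum())
    if n_const:
        log.info("coexpression_network: excluded %d constant genes", n_const)
    genes = [g for g, k in zip(matrix.genes, keep) if k]
    g = nx.Graph()
    g.add_nodes_from(genes)
    if len(genes) >= 2:
        r = np.atleast_2d(np.corrcoef(vals[keep]))
        iu, ju = np.where(np.triu(np.abs(r) >= r_threshold, k=1))
        for a, b in zip(iu, ju):
            g.add_edge(genes[a], genes[b])
    return g


def save_graphml(model: NetworkModel, path: str | Path) -> None:
    nx.write_graphml(model.graph, path)


def model_edge_table(model: NetworkModel) -> pd.DataFrame:
    rows = [{"geneA": a, "geneB": b} for a, b in
            sorted(tuple(sorted(e)) for e in model.graph.edges)]
    return pd.DataFrame(rows, columns=["geneA", "geneB"])
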