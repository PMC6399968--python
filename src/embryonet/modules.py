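"""Overlapping module detection by a restart-walk community landscape.

Every node seeds a random walk with restart; the per-node influence vectors
are summed into a landscape height.  Each node also defines a candidate
local community: the minimum-conductance prefix of its influence-ordered
support.  Deduplicated candidates become overlapping modules with graded
(influence-normalised) memberships, ranked into a hierarchy by a centrality
score — the membership-weighted closeness of their members, i.e. proximity
to the centre of the network.  The most central member labels the module
("metanode").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class Module:
    metanode: str
    members: frozenset
    membership: dict  # gene -> weight in (0, 1]
    centrality_score: float
    top_members: list = field(default_factory=list)
    seed: str = ""  # the restart-walk seed whose sweep defined the module


@dataclass
class ModuleSet:
    modules: list  # ordered by centrality_score desc, ties by metanode
    entity: str = ""  # stage or cell the network belongs to

    def __iter__(self):
        return iter(self.modules)

    def __len__(self):
        return len(self.modules)

    def member_sets(self) -> list[frozenset]:
        return [m.members for m in self.modules]

    def to_table(self) -> pd.DataFrame:
        rows = []
        for rank, m in enumerate(self.modules, start=1):
            for gene in sorted(m.members, key=lambda g: (-m.membership[g], g)):
                rows.append({"rank": rank, "metanode": m.metanode, "member": gene,
                             "weight": m.membership[gene],
                             "centrality_score": m.centrality_score})
        return pd.DataFrame(rows, columns=["rank", "metanode", "member", "weight",
                                           "centrality_score"])


def influence_landscape(graph: nx.Graph, restart: float = 0.15,
                        tol: float = 1e-10, max_iter: int = 10_000
                        ) -> tuple[pd.Series, pd.DataFrame]:
    """Restart-walk influence matrix and landscape heights.

    For each seed node v the personalised restart-walk stationary vector
    pi_v solves pi = restart * e_v + (1-restart) * P^T pi with P the simple
    random-walk transition matrix; the landscape height of node u is
    h(u) = sum_v pi_v(u).  Computed by (vectorised) power iteration to
    ``tol``.  Heights are strictly positive on a connected graph.

    Returns (heights indexed by node, influence DataFrame with
    influence.loc[u, v] = pi_v(u)).
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    a = nx.to_numpy_array(graph, nodelist=nodes)
    deg = a.sum(axis=1)
    deg[deg == 0] = 1.0  # isolated nodes restart in place
    pt = (a / deg[:, None]).T  # column v of P^T spreads from v's neighbours

    pi = np.eye(n)
    target = restart * np.eye(n)
    for _ in range(max_iter):
        nxt = target + (1.0 - restart) * pt @ pi
        if np.max(np.abs(nxt - pi)) < tol:
            pi = nxt
            break
        pi = nxt
    influence = pd.DataFrame(pi, index=nodes, columns=nodes)
    heights = pd.Series(pi.sum(axis=1), index=nodes, name="height")
    return heights, influence


def _closeness(graph: nx.Graph) -> dict:
    return nx.closeness_centrality(graph)


def _sweep_community(graph: nx.Graph, vec: pd.Series, adj: dict, two_m: int,
                     support_frac: float, phi_max: float) -> frozenset:
    """Minimum-conductance prefix of the influence-ordered support.

    The support is every node holding at least ``support_frac`` of the
    vector's maximum influence; nodes are swept in decreasing influence per
    degree and the lowest-conductance proper prefix is taken.  If no prefix
    beats ``phi_max`` (no community-scale cut exists, e.g. a clique-like
    graph) the whole support is the module.
    """
    support = [u for u in vec.index if vec[u] >= support_frac * vec.max()]
    order = sorted(support, key=lambda u: (-vec[u] / max(graph.degree(u), 1), u))
    inset: set = set()
    vol = cut = 0
    best = (np.inf, None)
    for i, u in enumerate(order):
        vol += graph.degree(u)
        cut += graph.degree(u) - 2 * len(adj[u] & inset)
        inset.add(u)
        denom = min(vol, two_m - vol)
        if denom <= 0:
            continue
        phi = cut / denom
        if phi < best[0]:
            best = (phi, i + 1)
    if best[1] is None or best[0] > phi_max:
        return frozenset(support)
    return frozenset(order[: best[1]])


def extract_modules(graph: nx.Graph, heights: pd.Series | None = None,
                    influence: pd.DataFrame | None = None,
                    max_modules: int | None = None,
                    membership_threshold: float = 0.05,
                    phi_max: float = 0.5,
                    restart: float = 0.15, entity: str = "") -> ModuleSet:
    """Overlapping modules from the influence landscape.

    Every node seeds a candidate local community: the support of its restart
    walk (nodes with >= ``membership_threshold`` of the maximum influence) is
    swept in decreasing influence per degree and cut at the minimum-
    conductance prefix.  Identical candidates are deduplicated (keeping the
    highest-landscape seed); membership weights are the seed's influence
    normalised to (0, 1].  Every node is attached to its best-membership
    module even when it reaches no candidate, so the modules cover the
    network.  Modules are ranked by membership-weighted closeness — proximity
    to the network centre — and optionally truncated to ``max_modules``.
    """
    if heights is None or influence is None:
        heights, influence = influence_landscape(graph, restart=restart)
    nodes = list(heights.index)
    adj = {v: set(graph.neighbors(v)) for v in nodes}
    two_m = 2 * graph.number_of_edges()

    candidates: dict[frozenset, str] = {}
    for seed in nodes:
        members = _sweep_community(graph, influence[seed], adj, two_m,
                                   membership_threshold, phi_max)
        prev = candidates.get(members)
        if prev is None or (-heights[seed], seed) < (-heights[prev], prev):
            candidates[members] = seed

    closeness = _closeness(graph)
    raw = [(seed, members, {u: float(influence.at[u, seed] / influence[seed].max())
                            for u in nodes})
           for members, seed in sorted(candidates.items(), key=lambda kv: kv[1])]

    # coverage: attach nodes missing from every candidate to their
    # argmax-membership module
    covered = set().union(*(m for _, m, _ in raw)) if raw else set()
    for u in nodes:
        if u in covered:
            continue
        best_i = max(range(len(raw)), key=lambda i: (raw[i][2][u], raw[i][0]))
        seed, members, membership = raw[best_i]
        raw[best_i] = (seed, members | {u}, membership)

    modules = []
    for seed, members, membership in raw:
        kept = {u: membership[u] for u in members}
        score = float(sum(w * closeness[u] for u, w in kept.items()))
        ranked = sorted(kept, key=lambda u: (-kept[u] * closeness[u], u))
        modules.append(Module(metanode=ranked[0], members=frozenset(kept),
                              membership=kept, centrality_score=score,
                              top_members=ranked, seed=seed))
    modules.sort(key=lambda m: (-m.centrality_score, m.metanode))
    if max_modules is not None:
        modules = modules[:max_modules]
    return ModuleSet(modules, entity=entity)


def membership_weight(influence: pd.DataFrame, module: Module, gene: str) -> float:
    """Graded membership of any node in a module: the module seed's influence
    at the node, normalised by the vector maximum.  Nonzero for every node
    connected to the seed's component."""
    if gene in module.membership:
        return module.membership[gene]
    seed = module.seed or module.metanode
    if seed not in influence.columns:
        return 0.0
    vec = influence[seed]
    return float(vec[gene] / vec.max())


def rank_module_members(module: Module, k: int = 10) -> list[str]:
    """Top-k most centrally connected members (metanode first)."""
    if not module.members:
        raise ValueError("empty module")
    return module.top_members[:k]
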