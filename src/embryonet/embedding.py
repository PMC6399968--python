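"""Low-dimensional embeddings of global expression profiles and
nearest-lineage assignment of blastomeres to ICM/TE references.

PCA works on the gene-centered sample x gene matrix; Isomap builds a
symmetric k-nearest-neighbour graph, takes all-pairs shortest-path geodesics
and applies classical multidimensional scaling.  With k = n-1 the geodesics
reduce to Euclidean distances and Isomap coincides with classical MDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import pdist, squareform

from .io import ExpressionMatrix

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # samples x dims (dim1..dimd)
    method: str
    explained: list = field(default_factory=list)  # per-dim variance fraction
    neighbour_k: int | None = None
    residual_variance: list = field(default_factory=list)
    lineage_assignment: pd.DataFrame | None = None


def _sample_matrix(matrix: ExpressionMatrix) -> np.ndarray:
    """Samples x genes, centered per gene."""
    x = matrix.values.to_numpy(float).T
    return x - x.mean(axis=0, keepdims=True)


def pca_embed(matrix: ExpressionMatrix, d: int = 2) -> EmbeddingResult:
    """Principal-component coordinates of the samples.

    Signs are fixed so each component's largest-magnitude gene loading is
    positive; explained-variance fractions accompany the coordinates.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least 2 samples")
    x = _sample_matrix(matrix)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if d > rank:
        raise ValueError(f"d={d} exceeds matrix rank {rank}")
    flip = np.sign(vt[np.arange(len(s)), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    coords = (u * s) * flip
    total = float((s ** 2).sum())
    explained = [float(si ** 2 / total) for si in s[:d]]
    frame = pd.DataFrame(coords[:, :d], index=matrix.samples,
                         columns=[f"dim{i+1}" for i in range(d)])
    return EmbeddingResult(frame, "pca", explained=explained)


def classical_mds(dist: np.ndarray, d: int) -> tuple[np.ndarray, list, list]:
    """Classical (Torgerson) MDS of a distance matrix.

    Negative eigenvalues are dropped; residual variance per retained
    dimension is 1 − cumulative eigenvalue fraction of the positive spectrum.
    """
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > max(w.max(), 0) * 1e-12
    w_pos, v_pos = w[pos], v[:, pos]
    if d > len(w_pos):
        raise ValueError(f"d={d} exceeds positive MDS spectrum ({len(w_pos)})")
    coords = v_pos[:, :d] * np.sqrt(w_pos[:d])
    total = float(w_pos.sum())
    explained = [float(wi / total) for wi in w_pos[:d]]
    residual = [1.0 - float(w_pos[: i + 1].sum() / total) for i in range(d)]
    return coords, explained, residual


def isomap_embed(matrix: ExpressionMatrix, k_neighbours: int = 5, d: int = 2
                 ) -> EmbeddingResult:
    """Isomap: kNN graph -> geodesic distances -> classical MDS.

    The kNN graph is symmetrised (an edge if either endpoint lists the
    other).  A disconnected graph is bridged through the single closest
    inter-component sample pair (logged) so geodesics are finite.
    """
    n = len(matrix.samples)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if k_neighbours < 1 or k_neighbours > n - 1:
        raise ValueError("k_neighbours must be in [1, n_samples-1]")
    x = _sample_matrix(matrix)
    dist = squareform(pdist(x))
    order = np.argsort(dist, axis=1, kind="stable")
    adj = np.full_like(dist, np.inf)
    for i in range(n):
        for j in order[i, 1 : k_neighbours + 1]:
            adj[i, j] = dist[i, j]
            adj[j, i] = dist[j, i]
    np.fill_diagonal(adj, 0.0)

    finite = np.where(np.isinf(adj), 0.0, adj)
    mask = (~np.isinf(adj)) & (adj > 0)
    n_comp, labels = connected_components(mask, directed=False)
    while n_comp > 1:
        best = None
        for a in range(n_comp):
            ia = np.where(labels == a)[0]
            for b in range(a + 1, n_comp):
                ib = np.where(labels == b)[0]
                sub = dist[np.ix_(ia, ib)]
                i_min, j_min = np.unravel_index(np.argmin(sub), sub.shape)
                cand = (float(sub[i_min, j_min]), int(ia[i_min]), int(ib[j_min]))
                if best is None or cand < best:
                    best = cand
        dmin, i, j = best
        log.info("isomap_embed: bridging components via %s-%s (d=%.3g)",
                 matrix.samples[i], matrix.samples[j], dmin)
        mask[i, j] = mask[j, i] = True
        finite[i, j] = finite[j, i] = dmin
        n_comp, labels = connected_components(mask, directed=False)

    weights = np.where(mask, finite, 0.0)
    geo = shortest_path(weights, method="D", directed=False, unweighted=False)
    coords, explained, residual = classical_mds(geo, d)
    frame = pd.DataFrame(coords, index=matrix.samples,
                         columns=[f"dim{i+1}" for i in range(d)])
    return EmbeddingResult(frame, "isomap", explained=explained,
                           neighbour_k=k_neighbours, residual_variance=residual)


def assign_lineage(embedding: EmbeddingResult, reference_labels: dict,
                   query_cells: list[str], classes: tuple = ("ICM", "TE")
                   ) -> pd.DataFrame:
    """Nearest reference-class centroid assignment in embedding coordinates.

    Each query gets the class of the closer centroid, distances to both, and
    the margin |d_ICM − d_TE|; exact ties are labelled 'unassigned'.
    """
    coords = embedding.coordinates
    centroids = {}
    for cls in classes:
        members = [s for s, c in reference_labels.items() if c == cls]
        if not members:
            raise ValueError(f"no reference samples for class {cls!r}")
        centroids[cls] = coords.loc[members].to_numpy(float).mean(axis=0)
    rows = []
    for cell in query_cells:
        point = coords.loc[cell].to_numpy(float)
        dists = {cls: float(np.linalg.norm(point - c)) for cls, c in centroids.items()}
        d_sorted = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))
        margin = abs(d_sorted[0][1] - d_sorted[-1][1])
        call = d_sorted[0][0] if d_sorted[0][1] < d_sorted[1][1] else UNASSIGNED
        rows.append({"cell": cell, "call": call,
                     **{f"d_{cls}": dists[cls] for cls in classes},
                     "margin": margin})
    table = pd.DataFrame(rows).set_index("cell")
    embedding.lineage_assignment = table
    return table
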