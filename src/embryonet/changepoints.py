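"""Change-point segmentation of short developmental expression series.

Each gene's ordered series (stage means, or the replicate sequence with
stages contiguous) is segmented by a mean-shift model: breakpoints minimise
the total within-segment sum of squared deviations plus a per-breakpoint
penalty.  Series are short (a handful of stages), so the optimum over all
segmentations is found exactly by dynamic programming.  Segment values are
then replaced by their interval averages and genes are clustered into
change-point groups by the shape of the averaged profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .io import ExpressionMatrix


@dataclass
class ChangePointProfile:
    gene: str
    series: list
    breakpoints: list  # breakpoint i splits positions i | i+1 (1-based)
    segment_means: list
    group: int | None = None
    label: str = ""


@dataclass
class ChangePointGroups:
    k: int
    assignment: dict  # gene -> group (1..k)
    group_profiles: pd.DataFrame  # group x positions, mean averaged profile
    profiles: dict = field(default_factory=dict)  # gene -> ChangePointProfile


def default_penalty(series: np.ndarray) -> float:
    """BIC-like penalty 2·sigma²·log(n), with sigma estimated from the MAD of
    first differences (robust to the steps themselves)."""
    x = np.asarray(series, float)
    n = len(x)
    if n < 2:
        return 0.0
    diffs = np.diff(x)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    sigma = 1.4826 * mad / np.sqrt(2.0)
    if sigma == 0:
        sigma = x.std() / np.sqrt(2.0)
    return float(2.0 * sigma ** 2 * np.log(n)) if sigma > 0 else 0.0


def segmentation_cost(series: np.ndarray, breakpoints: list[int], penalty: float) -> float:
    """Total within-segment SSE plus penalty per breakpoint."""
    x = np.asarray(series, float)
    bounds = [0, *breakpoints, len(x)]
    cost = 0.0
    for a, b in zip(bounds, bounds[1:]):
        seg = x[a:b]
        cost += float(((seg - seg.mean()) ** 2).sum())
    return cost + penalty * len(breakpoints)


def detect_changepoints(series, penalty: float | None = None,
                        allowed: list[int] | None = None) -> list[int]:
    """Exact mean-shift segmentation by dynamic programming.

    Returns breakpoint positions (1-based: breakpoint ``i`` splits ``i|i+1``)
    minimising within-segment SSE + penalty x (#breakpoints).  ``allowed``
    restricts candidate positions (used to pin breaks to stage boundaries on
    replicate series).  A constant series yields no breakpoints.  Ties are
    broken toward fewer, earlier breakpoints.
    """
    x = np.asarray(series, float)
    n = len(x)
    if n < 2:
        return []
    if penalty is None:
        penalty = default_penalty(x)
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    allowed_set = set(range(1, n)) if allowed is None else set(allowed)
    if not allowed_set <= set(range(1, n)):
        raise ValueError("allowed breakpoints out of series bounds")

    # prefix sums for O(1) segment SSE
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x ** 2)])

    def sse(a: int, b: int) -> float:  # positions a..b-1
        m = b - a
        tot = s1[b] - s1[a]
        return float(s2[b] - s2[a] - tot * tot / m)

    # best[j] = (cost, n_breaks, breaks tuple) for prefix of length j
    best: list[tuple] = [(0.0, 0, ())] + [None] * n
    for j in range(1, n + 1):
        cands = []
        for a in range(j):
            if a != 0 and a not in allowed_set:
                continue
            prev = best[a]
            if prev is None:
                continue
            nb = prev[1] + (1 if a > 0 else 0)
            cost = prev[0] + sse(a, j) + (penalty if a > 0 else 0.0)
            breaks = prev[2] + ((a,) if a > 0 else ())
            cands.append((cost, nb, breaks))
        best[j] = min(cands, key=lambda t: (round(t[0], 12), t[1], t[2]))
    return list(best[n][2])


def segment_average(series, breakpoints: list[int]) -> np.ndarray:
    """Replace every value by the mean of its segment; same length out."""
    x = np.asarray(series, float)
    bounds = [0, *sorted(breakpoints), len(x)]
    if any(b <= a for a, b in zip(bounds, bounds[1:])):
        raise ValueError("invalid breakpoints")
    out = np.empty_like(x)
    for a, b in zip(bounds, bounds[1:]):
        out[a:b] = x[a:b].mean()
    return out


def profile_matrix(matrix: ExpressionMatrix, per_stage_mean: bool = True) -> pd.DataFrame:
    """Gene x position series for segmentation: stage means (default) or the
    replicate sequence in stage-contiguous order."""
    order = []
    for stage in matrix.stages:
        order.extend(matrix.samples_of_stage(stage))
    vals = matrix.values[order]
    if not per_stage_mean:
        return vals.copy()
    cols = {}
    for stage in matrix.stages:
        cols[stage] = vals[matrix.samples_of_stage(stage)].mean(axis=1)
    return pd.DataFrame(cols)


def stage_boundaries(matrix: ExpressionMatrix) -> list[int]:
    """Breakpoint positions between stage blocks of the replicate-ordered
    series (1-based: a boundary after the i-th sample)."""
    bounds = []
    total = 0
    for stage in matrix.stages[:-1]:
        total += len(matrix.samples_of_stage(stage))
        bounds.append(total)
    return bounds


def segment_profiles(profiles: pd.DataFrame, penalty: float | None = None,
                     allowed: list[int] | None = None) -> dict[str, ChangePointProfile]:
    out = {}
    for gene, row in profiles.iterrows():
        series = row.to_numpy(float)
        bps = detect_changepoints(series, penalty=penalty, allowed=allowed)
        averaged = segment_average(series, bps)
        bounds = [0, *bps, len(series)]
        means = [float(series[a:b].mean()) for a, b in zip(bounds, bounds[1:])]
        out[gene] = ChangePointProfile(gene, list(series), bps, means)
    return out


def segment_stage_series(matrix: ExpressionMatrix, genes: list[str] | None = None,
                         penalty: float | None = None
                         ) -> tuple[dict[str, ChangePointProfile], pd.DataFrame, dict]:
    """Default segmentation path: replicate-ordered series, breaks pinned to
    stage boundaries (developmental transitions happen between stages, not
    between replicates).

    Returns (profiles, averaged frame, per-gene stage-index breakpoints where
    index i means the step occurs entering the i-th stage, 1-based).
    """
    bounds = stage_boundaries(matrix)
    profiles_mat = profile_matrix(matrix, per_stage_mean=False)
    if genes is not None:
        profiles_mat = profiles_mat.loc[list(genes)]
    profs = segment_profiles(profiles_mat, penalty=penalty, allowed=bounds)
    averaged = pd.DataFrame({g: segment_average(p.series, p.breakpoints)
                             for g, p in profs.items()}).T
    averaged.columns = profiles_mat.columns
    stage_bps = {g: [bounds.index(b) + 1 for b in p.breakpoints]
                 for g, p in profs.items()}
    return profs, averaged, stage_bps


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Row-standardise so Euclidean distance is monotone in correlation
    distance (||z_i - z_j||² = 2(1 - r_ij)); constant rows map to zero."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return z / np.sqrt(x.shape[1])


def cluster_changepoint_groups(
    averaged: pd.DataFrame,
    k: int = 7,
    method: str = "average",
    metric: str = "correlation",
    profiles: dict[str, ChangePointProfile] | None = None,
) -> ChangePointGroups:
    """Hierarchical clustering of segment-averaged profiles into k groups.

    The default correlation metric is computed on row-standardised profiles
    (constant profiles standardise to zero, grouping together) so the
    linkage is defined for every gene and deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(averaged):
        raise ValueError(f"k={k} exceeds number of genes {len(averaged)}")
    x = averaged.to_numpy(float)
    feats = _standardize_rows(x) if metric == "correlation" else x
    if len(averaged) == k:
        labels = np.arange(1, k + 1)
    else:
        z = linkage(feats, method=method, metric="euclidean")
        labels = fcluster(z, t=k, criterion="maxclust")
    assignment = dict(zip(averaged.index, (int(v) for v in labels)))
    group_profiles = (
        pd.DataFrame(x, index=averaged.index, columns=averaged.columns)
        .groupby(pd.Series(assignment))
        .mean()
    )
    groups = ChangePointGroups(k, assignment, group_profiles, profiles or {})
    if profiles:
        for gene, prof in profiles.items():
            prof.group = assignment.get(gene)
    return groups


def label_changepoint_groups(groups: ChangePointGroups,
                             per_stage_presence: dict[str, set],
                             stage_order: list[str]) -> dict[int, str]:
    """Maternal/embryonic labels for change-point groups from presence calls.

    A group's member genes vote on a rule table over stage presence: expressed
    in the oocyte (first stage) and not later -> maternal-only; expressed in
    the oocyte and again later -> maternal+embryonic; absent from the oocyte
    and first expressed at stage j -> EGA-early/mid/late by the tercile of j.
    """
    first = stage_order[0]
    later = stage_order[1:]
    n_later = len(later)

    def gene_label(gene: str) -> str:
        in_oocyte = gene in per_stage_presence.get(first, set())
        later_hits = [s for s in later if gene in per_stage_presence.get(s, set())]
        if in_oocyte:
            return "maternal+embryonic" if later_hits else "maternal-only"
        if not later_hits:
            return "not-expressed"
        j = later.index(later_hits[0])
        tercile = 3 * j // max(n_later, 1)
        return ("EGA-early", "EGA-mid", "EGA-late")[min(tercile, 2)]

    labels: dict[int, str] = {}
    for group in sorted(set(groups.assignment.values())):
        members = [g for g, grp in groups.assignment.items() if grp == group]
        votes = pd.Series([gene_label(g) for g in members]).value_counts()
        labels[group] = str(votes.index[0])
    for gene, prof in groups.profiles.items():
        if prof.group is not None:
            prof.label = labels[prof.group]
    return labels


def changepoint_table(profiles: dict[str, ChangePointProfile]) -> pd.DataFrame:
    rows = []
    for gene in profiles:
        p = profiles[gene]
        rows.append({
            "gene": gene,
            "breakpoints": ";".join(map(str, p.breakpoints)),
            "segment_means": ";".join(f"{m:.6g}" for m in p.segment_means),
            "group": p.group if p.group is not None else "",
            "label": p.label,
        })
    return pd.DataFrame(rows)
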