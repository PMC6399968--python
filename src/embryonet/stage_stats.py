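"""Stage-level statistics: presence calls, one-way ANOVA differential
expression with Benjamini-Hochberg control, projection-score variance
filtering, and PCA-plane outlier removal.

Presence at a stage follows the "at least 75% (or two of three) samples"
rule: a gene is expressed at a stage if it is detected in at least the
nearest integer to ``stage_fraction * n`` of the stage's ``n`` samples
(half rounded up), which gives 2 of 3 and 3 of 4 at the default fraction —
the two readings the rule is quoted with.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, PresenceMatrix

log = logging.getLogger(__name__)


@dataclass
class StageDEResult:
    table: pd.DataFrame  # gene-indexed: F, p, q, mean_<stage>..., degenerate
    threshold: float = 0.05
    mode: str = "omnibus"

    @property
    def de_genes(self) -> set:
        return set(self.table.index[self.table["q"] <= self.threshold])


@dataclass
class ProjectionFilter:
    cutoff_grid: list
    scores: dict  # cutoff -> projection score
    chosen_cutoff: float
    retained_genes: list
    gene_statistic: pd.Series  # per-gene variance statistic (SD)


def call_presence(
    matrix: ExpressionMatrix,
    flags: pd.DataFrame | None = None,
    threshold: float | None = None,
    stage_fraction: float = 0.75,
) -> tuple[PresenceMatrix, dict]:
    """Per-sample detection calls plus per-stage expressed gene sets.

    Detection comes either from platform flags (0/1 DataFrame, same shape) or
    from an intensity threshold (value >= threshold).  A gene is "expressed
    at a stage" if detected in at least round(stage_fraction * n_samples)
    (half up, minimum 1) of that stage's samples: 2 of 3, 3 of 4.
    """
    if (flags is None) == (threshold is None):
        raise ValueError("supply exactly one of flags or threshold")
    if flags is not None:
        calls = flags.loc[matrix.genes, matrix.samples].astype(int)
        provenance = "flag-based"
    else:
        calls = (matrix.values >= threshold).astype(int)
        provenance = "threshold-based"
    presence = PresenceMatrix(calls, provenance=provenance)

    per_stage: dict[str, set] = {}
    for stage in matrix.stages:
        samples = matrix.samples_of_stage(stage)
        if not samples:
            raise ValueError(f"stage {stage!r} has no samples")
        need = max(1, math.floor(stage_fraction * len(samples) + 0.5))
        counts = calls[samples].sum(axis=1)
        per_stage[stage] = set(counts.index[counts >= need])
    return presence, per_stage


def _anova_f(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised one-way fixed-effects ANOVA over genes (rows).

    Returns (F, p, degenerate) where degenerate genes (zero between- and
    within-group variance) get p = 1.
    """
    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    n = int(ns.sum())
    grand = np.hstack(groups).mean(axis=1)
    means = np.column_stack([g.mean(axis=1) for g in groups])
    ssb = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.zeros_like(ssb)
    for g, m in zip(groups, means.T):
        ssw += ((g - m[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    degenerate = (ssw <= 1e-300) & (ssb <= 1e-300)
    p = np.where(np.isfinite(f), stats.f.sf(np.where(np.isfinite(f), f, 0.0), df_b, df_w), 0.0)
    # zero within-group variance with real between-group signal -> p ~ 0
    p = np.where(degenerate, 1.0, p)
    f = np.where(degenerate, 0.0, f)
    return f, p, degenerate


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(pvalues, method="fdr_bh")[1]


def anova_stage_de(
    matrix: ExpressionMatrix,
    stages: list[str] | None = None,
    threshold: float = 0.05,
    mode: str = "omnibus",
    reference_stage: str | None = None,
) -> StageDEResult:
    """Per-gene one-way ANOVA across stage groups with BH correction.

    ``mode='omnibus'`` tests all listed stages jointly; ``mode='pairwise'``
    tests ``reference_stage`` against each other stage separately and takes
    the per-gene minimum BH q over comparisons (each comparison is corrected
    over all genes).
    """
    stages = list(stages) if stages is not None else matrix.stages
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    groups = {s: matrix.values[matrix.samples_of_stage(s)].to_numpy(float) for s in stages}
    for s, g in groups.items():
        if g.shape[1] < 2:
            raise ValueError(f"stage {s!r} has fewer than 2 samples")

    table = pd.DataFrame(index=matrix.values.index)
    for s in stages:
        table[f"mean_{s}"] = groups[s].mean(axis=1)

    if mode == "omnibus":
        f, p, degenerate = _anova_f([groups[s] for s in stages])
        q = bh_qvalues(p)
    elif mode == "pairwise":
        ref = reference_stage or stages[0]
        others = [s for s in stages if s != ref]
        fs, ps, qs, degs = [], [], [], []
        for s in others:
            f_i, p_i, d_i = _anova_f([groups[ref], groups[s]])
            fs.append(f_i)
            ps.append(p_i)
            qs.append(bh_qvalues(p_i))
            degs.append(d_i)
        pick = np.argmin(np.column_stack(qs), axis=1)
        rows = np.arange(len(pick))
        f = np.column_stack(fs)[rows, pick]
        p = np.column_stack(ps)[rows, pick]
        q = np.column_stack(qs)[rows, pick]
        degenerate = np.column_stack(degs).all(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n_deg = int(degenerate.sum())
    if n_deg:
        log.info("anova_stage_de: %d degenerate genes set to p=1", n_deg)
    table.insert(0, "F", f)
    table.insert(1, "p", p)
    table.insert(2, "q", q)
    table["degenerate"] = degenerate
    return StageDEResult(table, threshold=threshold, mode=mode)


def projection_score(centered: np.ndarray, k_components: int,
                     n_permutations: int = 20, seed: int = 0) -> float:
    """Excess of the top-k singular-value energy fraction over its
    per-gene-permutation null expectation."""
    def energy(x: np.ndarray) -> float:
        s = np.linalg.svd(x, compute_uv=False)
        total = float((s ** 2).sum())
        return float((s[:k_components] ** 2).sum() / total) if total > 0 else 0.0

    rng = np.random.default_rng(seed)
    observed = energy(centered)
    null = []
    for _ in range(n_permutations):
        perm = np.array([rng.permutation(row) for row in centered])
        null.append(energy(perm))
    return observed - float(np.mean(null))


def projection_filter(
    matrix: ExpressionMatrix,
    cutoff: float,
    k_components: int = 2,
    cutoff_grid: list[float] | None = None,
    n_permutations: int = 20,
    seed: int = 0,
) -> ProjectionFilter:
    """Variance filter with a projection-score report.

    Genes are ranked by per-gene standard deviation; the cutoff (same scale)
    keeps genes with SD >= cutoff.  For each grid cutoff the projection score
    of the retained, per-gene-centered submatrix is the top-k singular-energy
    fraction minus its permutation-null mean.  The printed thresholds of
    array software live on proprietary scales, so cutoffs here are plain SD
    units.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    vals = matrix.values.to_numpy(float)
    sd = pd.Series(vals.std(axis=1, ddof=1), index=matrix.values.index)
    grid = sorted(set((cutoff_grid or []) + [cutoff]))
    scores = {}
    for c in grid:
        keep = sd.index[sd >= c]
        if len(keep) < 3:
            if c == cutoff:
                raise ValueError(f"cutoff {c} retains fewer than 3 genes")
            scores[c] = float("nan")
            continue
        sub = matrix.values.loc[keep].to_numpy(float)
        centered = sub - sub.mean(axis=1, keepdims=True)
        scores[c] = projection_score(centered, k_components, n_permutations, seed)
    retained = list(sd.index[sd >= cutoff])
    return ProjectionFilter(grid, scores, cutoff, retained, sd)


def remove_outliers(matrix: ExpressionMatrix, z_cutoff: float = 3.0
                    ) -> tuple[ExpressionMatrix, list[str]]:
    """Drop samples far from the centroid in the top-2 PC plane.

    Distances from the sample centroid in PC1/PC2 are robust-z scored
    (median/MAD); samples above ``z_cutoff`` are removed in a single pass.
    Refuses to remove more than half the samples.
    """
    if len(matrix.samples) < 4:
        raise ValueError("need at least 4 samples")
    x = matrix.values.to_numpy(float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    coords = x @ vt[:2].T
    dist = np.linalg.norm(coords - coords.mean(axis=0, keepdims=True), axis=1)
    med = np.median(dist)
    mad = np.median(np.abs(dist - med))
    scale = 1.4826 * mad if mad > 0 else (dist.std() or 1.0)
    z = (dist - med) / scale
    removed = [s for s, zi in zip(matrix.samples, z) if zi > z_cutoff]
    if len(removed) > len(matrix.samples) / 2:
        raise ValueError("outlier rule would remove more than half the samples")
    kept = [s for s in matrix.samples if s not in removed]
    if removed:
        log.info("remove_outliers: dropped %s", removed)
    return matrix.subset_samples(kept), removed
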