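"""Single-cell expression barcodes and qPCR processing.

A barcode is an absolute present/absent call per gene per cell.  Calls come
from a two-component Gaussian mixture over log intensities (unexpressed vs
expressed); each gene is fitted by EM across the pooled cells and reference
samples, with a fallback to the pooled-mixture midpoint threshold for
degenerate per-gene fits.  Downstream rules are pinned to the study's stated
thresholds: the variable-gene filter keeps genes present in 2-5 of the 8
blastomeres, qPCR transcripts count as expressed at 37 or fewer cycles
(ΔCt = 40 − Ct), and a cell enters the qPCR analysis only with more than 3
expressed targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .io import ExpressionMatrix, GenePanel, PresenceMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# two-component mixture caller
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    mean_unexpressed: float
    sd_unexpressed: float
    mean_expressed: float
    sd_expressed: float
    weight_expressed: float
    converged: bool = True

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.mean_unexpressed + self.mean_expressed)


@dataclass
class BarcodeMatrix:
    calls: pd.DataFrame  # genes x cells, 0/1
    gene_provenance: pd.Series  # gene -> mixture | threshold

    def as_presence(self) -> PresenceMatrix:
        return PresenceMatrix(self.calls, provenance="barcode")

    def write(self, path) -> None:
        out = self.calls.copy()
        out.insert(0, "gene", out.index)
        out["provenance"] = self.gene_provenance.loc[out.index].to_numpy()
        out.to_csv(path, sep="\t", index=False)


def fit_mixture(values: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> MixtureFit:
    """EM fit of a 1-D two-Gaussian mixture, initialised from the quartiles.

    Quartile initialisation makes the fit equivariant under adding a constant
    to all values, so barcode calls are location-shift invariant.
    """
    x = np.asarray(values, float)
    if x.std() == 0:
        raise ValueError("cannot fit a mixture to constant values")
    mu = np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)])
    if mu[0] == mu[1]:
        mu = np.array([x.min(), x.max()])
    sd = np.array([x.std(), x.std()])
    w = np.array([0.5, 0.5])
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        dens = np.array([wi * stats.norm.pdf(x, mi, max(si, 1e-6))
                         for wi, mi, si in zip(w, mu, sd)])
        total = dens.sum(axis=0)
        total[total == 0] = 1e-300
        resp = dens / total
        ll = float(np.log(total).sum())
        nk = resp.sum(axis=1)
        if (nk < 1e-10).any():
            break
        w = nk / len(x)
        mu = (resp * x).sum(axis=1) / nk
        sd = np.sqrt((resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk)
        sd = np.maximum(sd, 1e-6)
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
    lo, hi = (0, 1) if mu[0] <= mu[1] else (1, 0)
    return MixtureFit(float(mu[lo]), float(sd[lo]), float(mu[hi]), float(sd[hi]),
                      float(w[hi]), converged)


def posterior_expressed(x: np.ndarray, fit: MixtureFit) -> np.ndarray:
    """Posterior probability that each value comes from the expressed component."""
    x = np.asarray(x, float)
    d_hi = fit.weight_expressed * stats.norm.pdf(x, fit.mean_expressed, fit.sd_expressed)
    d_lo = (1 - fit.weight_expressed) * stats.norm.pdf(x, fit.mean_unexpressed,
                                                       fit.sd_unexpressed)
    total = d_hi + d_lo
    out = np.where(total > 0, d_hi / np.where(total > 0, total, 1.0), 0.5)
    # far in a tail both densities underflow; fall back to the midpoint side
    return np.where(total > 0, out, (x >= fit.midpoint).astype(float))


def _fit_is_degenerate(fit: MixtureFit, n_points: int, min_points: int,
                       reference_sep: float | None = None) -> bool:
    """A per-gene fit is only trusted when clearly bimodal: well separated
    components (>= 2 pooled SDs, and not far tighter than the pooled global
    separation) each supported by >= 2 points."""
    if n_points < min_points:
        return True
    sep = fit.mean_expressed - fit.mean_unexpressed
    pooled_sd = 0.5 * (fit.sd_expressed + fit.sd_unexpressed)
    min_w = 2.0 / n_points
    if (not fit.converged) or sep < 2.0 * pooled_sd:
        return True
    if not (min_w <= fit.weight_expressed <= 1.0 - min_w):
        return True
    if reference_sep is not None and sep < 0.5 * reference_sep:
        return True
    return False


def call_barcode(matrix: ExpressionMatrix, cells: list[str] | None = None,
                 min_points: int = 6) -> BarcodeMatrix:
    """Binary present/absent barcode from continuous log intensities.

    Per gene, a two-component mixture is fitted across the pooled samples; a
    value is called present when the posterior of the expressed component is
    >= 0.5.  Genes with degenerate fits (too few points, unseparated or
    vanishing components) fall back to the midpoint threshold of the pooled
    global mixture.  Per-gene decision provenance is recorded.
    """
    cols = cells if cells is not None else matrix.samples
    if len(cols) < 2:
        raise ValueError("need at least 2 cells")
    vals = matrix.values[cols]
    pooled = matrix.values.to_numpy(float).ravel()
    if pooled.std() == 0:
        raise ValueError("matrix is constant; no mixture structure to call")
    global_fit = fit_mixture(pooled)
    threshold = global_fit.midpoint
    global_sep = global_fit.mean_expressed - global_fit.mean_unexpressed

    calls = pd.DataFrame(0, index=vals.index, columns=cols)
    provenance = pd.Series("threshold", index=vals.index)
    for gene, row in vals.iterrows():
        x = row.to_numpy(float)
        use_mixture = False
        if x.std() > 0 and len(x) >= min_points:
            try:
                fit = fit_mixture(x)
            except ValueError:
                fit = None
            if fit is not None and not _fit_is_degenerate(fit, len(x), min_points,
                                                          reference_sep=global_sep):
                calls.loc[gene] = (posterior_expressed(x, fit) >= 0.5).astype(int)
                provenance[gene] = "mixture"
                use_mixture = True
        if not use_mixture:
            calls.loc[gene] = (x >= threshold).astype(int)
    n_mix = int((provenance == "mixture").sum())
    log.info("call_barcode: %d mixture fits, %d threshold fallbacks",
             n_mix, len(provenance) - n_mix)
    return BarcodeMatrix(calls, provenance)


# ---------------------------------------------------------------------------
# barcode-derived gene filters and panels
# ---------------------------------------------------------------------------

def blastomere_variable_filter(barcode: BarcodeMatrix | PresenceMatrix,
                               min_cells: int = 2, max_cells: int = 5) -> set:
    """Genes present in between min_cells and max_cells cells (inclusive) —
    the variably expressed transcripts used for single-cell networks."""
    calls = barcode.calls
    counts = calls.sum(axis=1)
    return set(counts.index[(counts >= min_cells) & (counts <= max_cells)])


def panel_profile(calls: pd.DataFrame, panels: list[GenePanel]
                  ) -> dict[str, pd.DataFrame]:
    """Per-panel presence submatrix and per-entity counts.

    ``calls`` is a 0/1 genes x entities frame (cells, or stages from the 75%
    presence rule).  Panels with no measured genes are skipped with a
    warning.  Returns {panel name: submatrix with a trailing 'count' row}.
    """
    out = {}
    for panel in panels:
        measured = sorted(panel.members & set(calls.index))
        if not measured:
            log.warning("panel %s: no measured genes, skipped", panel.name)
            continue
        sub = calls.loc[measured].copy()
        counts = sub.sum(axis=0)
        sub.loc["count"] = counts
        out[panel.name] = sub
    return out


def stage_presence_calls(per_stage_sets: dict[str, set], genes: list[str]) -> pd.DataFrame:
    """Stage-level 0/1 frame from per-stage expressed gene sets."""
    return pd.DataFrame({s: [int(g in gs) for g in genes]
                         for s, gs in per_stage_sets.items()}, index=genes)


def group_cells_by_panel(calls: pd.DataFrame, panel: GenePanel | None = None,
                         k: int = 2) -> dict[str, int]:
    """Cluster cells into k groups by their binary panel barcodes.

    Distance is 1 − Jaccard between cell barcode vectors; average-linkage
    hierarchical clustering is cut at k.  Cells are processed in lexicographic
    order so ties resolve deterministically.
    """
    sub = calls
    if panel is not None:
        measured = sorted(panel.members & set(calls.index))
        if not measured:
            raise ValueError(f"panel {panel.name!r} has no measured genes")
        sub = calls.loc[measured]
    cells = sorted(sub.columns)
    if k > len(cells):
        raise ValueError(f"k={k} exceeds number of cells {len(cells)}")
    x = sub[cells].to_numpy(bool).T  # cells x genes
    if k == len(cells):
        return {c: i + 1 for i, c in enumerate(cells)}
    d = pdist(x, metric="jaccard")
    z = linkage(d, method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    return {c: int(l) for c, l in zip(cells, labels)}


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

@dataclass
class QPCRResult:
    delta_ct: pd.DataFrame  # cells x genes, ΔCt = 40 − mean Ct
    expressed: pd.DataFrame  # cells x genes bool (mean Ct <= 37)
    included_cells: list
    excluded_cells: list
    associations: pd.DataFrame  # geneA, geneB, chi2, p, significant


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square without continuity correction for a 2x2 table.

    Degenerate tables (a zero margin) carry no information: chi2 = 0, p = 1.
    """
    table = np.asarray(table, float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        log.warning("chi_square_2x2: expected count below 5")
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def process_qpcr(table: pd.DataFrame, min_expressed_genes: int = 4,
                 ct_expressed_max: float = 37.0, replicate_rule: str = "mean",
                 alpha: float = 0.05) -> QPCRResult:
    """Process a replicate Ct table into ΔCt profiles and gene associations.

    Input columns: ``cell, gene, ct_rep1[, ct_rep2, ...]``.  ΔCt = 40 − Ct
    (mean of replicates by default; ``replicate_rule='majority'`` instead
    requires a majority of replicates at or below the detection cycle).  A
    gene is expressed when detected with ``ct_expressed_max`` or fewer
    cycles; a cell is analysed only if it has at least ``min_expressed_genes``
    expressed targets (the strict reading of "greater than 3").  Associations
    between gene presence patterns across included cells use a Pearson
    chi-square without continuity correction.
    """
    rep_cols = [c for c in table.columns if c.startswith("ct_rep")]
    if not rep_cols:
        raise ValueError("no ct_rep* columns found")
    work = table.copy()
    cts = work[rep_cols].astype(float)
    if (cts <= 0).any().any():
        raise ValueError("Ct values must be positive")
    work["ct_mean"] = cts.mean(axis=1)
    if replicate_rule == "mean":
        work["expressed"] = work["ct_mean"] <= ct_expressed_max
    elif replicate_rule == "majority":
        work["expressed"] = (cts <= ct_expressed_max).sum(axis=1) > len(rep_cols) / 2
    else:
        raise ValueError(f"unknown replicate_rule {replicate_rule!r}")
    work["delta_ct"] = 40.0 - work["ct_mean"]

    delta = work.pivot_table(index="cell", columns="gene", values="delta_ct")
    expressed = work.pivot_table(index="cell", columns="gene", values="expressed",
                                 aggfunc="any").fillna(False).astype(bool)
    n_expr = expressed.sum(axis=1)
    included = sorted(n_expr.index[n_expr >= min_expressed_genes])
    excluded = sorted(set(expressed.index) - set(included))
    if excluded:
        log.info("process_qpcr: excluded cells %s", excluded)

    genes = sorted(expressed.columns)
    rows = []
    sub = expressed.loc[included]
    for i, ga in enumerate(genes):
        for gb in genes[i + 1:]:
            a, b = sub[ga].to_numpy(), sub[gb].to_numpy()
            tab = np.array([[int((a & b).sum()), int((a & ~b).sum())],
                            [int((~a & b).sum()), int((~a & ~b).sum())]])
            chi2, p = chi_square_2x2(tab)
            rows.append({"geneA": ga, "geneB": gb, "chi2": chi2, "p": p,
                         "significant": p <= alpha})
    assoc = pd.DataFrame(rows, columns=["geneA", "geneB", "chi2", "p", "significant"])
    return QPCRResult(delta, expressed, included, excluded, assoc)
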