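"""Synthetic study generator with planted ground truth.

Emulates the study design of a human preimplantation time course: four
ordered stages (oocyte, 4-cell, 8-cell, blastocyst) with a handful of
replicate embryos each, plus eight single blastomeres from one 8-cell embryo
and a few ICM/TE reference profiles.  Planted structure covers everything the
pipeline infers downstream:

* an interactome with dense, optionally overlapping planted modules on an
  Erdős–Rényi background;
* stage-wise expression as per-gene step functions over stage means (steps at
  planted change points, height ``de_effect_size``) plus Gaussian noise;
* blastomere intensity profiles containing two planted lineage groups
  (ICM-like / TE-like) separated by ``lineage_separation`` in log-intensity,
  with marker genes, housekeeping genes, and graded translation-initiation
  and epigenetic panels;
* qPCR Ct tables consistent with the planted barcodes.

All randomness flows from ``SyntheticConfig.seed`` through per-operation
substreams, so each generator is deterministic regardless of call order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenePanel, PresenceMatrix

DEFAULT_STAGES = ("oocyte", "4cell", "8cell", "blastocyst")
DEFAULT_REPLICATES = (4, 4, 3, 4)

# log2-intensity mixture for "unexpressed" vs "expressed" transcripts
UNEXPRESSED_MEAN = 4.0
EXPRESSED_MEAN = 8.0
INTENSITY_SD = 1.0

_STREAM_INTERACTOME = 1
_STREAM_STAGE = 2
_STREAM_BLASTOMERE = 3
_STREAM_QPCR = 4


@dataclass
class SyntheticConfig:
    n_genes: int = 300
    n_stages: int = 4
    replicates_per_stage: tuple = DEFAULT_REPLICATES
    n_blastomeres: int = 8
    n_planted_modules: int = 6
    module_size_range: tuple = (8, 15)
    module_overlap_frac: float = 0.2
    background_edge_prob: float = 0.01
    within_module_edge_prob: float = 0.9
    de_effect_size: float = 3.0
    noise_sd: float = 1.0
    de_background_frac: float = 0.5  # non-module genes with a planted step
    lineage_separation: float = 4.0
    changepoint_truth: dict | None = None  # gene -> list of breakpoint stage indices
    n_changepoint_classes: int | None = None
    n_markers_per_group: int = 30
    n_housekeeping: int = 20
    panel_size: int = 10
    n_reference_per_class: int = 3
    stage_names: tuple = DEFAULT_STAGES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stages < 2:
            raise ValueError("need at least 2 stages")
        if not (0.0 <= self.module_overlap_frac <= 1.0):
            raise ValueError("module_overlap_frac must be in [0,1]")
        for p in (self.background_edge_prob, self.within_module_edge_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("edge probabilities must be in [0,1]")
        lo, hi = self.module_size_range
        if lo < 3:
            raise ValueError("planted module sizes must be >= 3")
        if lo > hi:
            raise ValueError("module_size_range must be (min, max) with min <= max")
        if self.noise_sd < 0 or self.de_effect_size < 0 or self.lineage_separation < 0:
            raise ValueError("effect sizes and noise must be nonnegative")
        if isinstance(self.replicates_per_stage, int):
            self.replicates_per_stage = (self.replicates_per_stage,) * self.n_stages
        self.replicates_per_stage = tuple(self.replicates_per_stage)
        if len(self.replicates_per_stage) != self.n_stages:
            raise ValueError("replicates_per_stage must match n_stages")
        if len(self.stage_names) < self.n_stages:
            self.stage_names = tuple(f"stage{i+1}" for i in range(self.n_stages))
        self.stage_names = tuple(self.stage_names[: self.n_stages])

    @property
    def genes(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def cells(self) -> list[str]:
        return [f"B{i}" for i in range(1, self.n_blastomeres + 1)]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class SyntheticTruth:
    planted_modules: list = field(default_factory=list)  # list[frozenset]
    de_genes_per_stage: dict = field(default_factory=dict)  # stage -> set
    true_changepoints: dict = field(default_factory=dict)  # gene -> [breakpoints]
    changepoint_class: dict = field(default_factory=dict)  # gene -> class id
    blastomere_groups: dict = field(default_factory=dict)  # cell -> ICM-like|TE-like
    panel_truth: dict = field(default_factory=dict)  # panel -> {cell: count}
    marker_genes: dict = field(default_factory=dict)  # group -> [genes]
    housekeeping_genes: list = field(default_factory=list)
    true_barcode: dict = field(default_factory=dict)  # gene -> {cell: 0/1}
    step_signs: dict = field(default_factory=dict)  # gene -> [signs]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_modules": [sorted(m) for m in self.planted_modules],
            "de_genes_per_stage": {k: sorted(v) for k, v in self.de_genes_per_stage.items()},
            "true_changepoints": self.true_changepoints,
            "changepoint_class": self.changepoint_class,
            "blastomere_groups": self.blastomere_groups,
            "panel_truth": self.panel_truth,
            "marker_genes": self.marker_genes,
            "housekeeping_genes": list(self.housekeeping_genes),
            "true_barcode": self.true_barcode,
            "step_signs": self.step_signs,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_modules=[frozenset(m) for m in d["planted_modules"]],
            de_genes_per_stage={k: set(v) for k, v in d["de_genes_per_stage"].items()},
            true_changepoints=d["true_changepoints"],
            changepoint_class=d["changepoint_class"],
            blastomere_groups=d["blastomere_groups"],
            panel_truth=d["panel_truth"],
            marker_genes=d["marker_genes"],
            housekeeping_genes=d["housekeeping_genes"],
            true_barcode=d["true_barcode"],
            step_signs=d["step_signs"],
        )


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------

def _plant_module_members(config: SyntheticConfig, rng: np.random.Generator) -> list[frozenset]:
    genes = config.genes
    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_planted_modules)
    modules: list[list[str]] = []
    cursor = 0
    for i, size in enumerate(sizes):
        overlap = int(round(config.module_overlap_frac * size)) if i > 0 else 0
        overlap = min(overlap, len(modules[-1]) if modules else 0, size - 1)
        start = cursor - overlap
        members = genes[start : start + size] if start + size <= len(genes) else None
        if members is None or len(members) < size:
            raise ValueError(
                f"infeasible config: planted modules need more than {config.n_genes} genes"
            )
        modules.append(members)
        cursor = start + size
    return [frozenset(m) for m in modules]


def generate_interactome(config: SyntheticConfig) -> tuple[nx.Graph, SyntheticTruth]:
    """Planted-partition interactome: dense planted modules over an ER background.

    Returns an undirected simple connected graph plus a truth object whose
    ``planted_modules`` are the planted gene sets.  A spanning backbone is
    added between components if the sampled graph is disconnected.
    """
    rng = config.rng(_STREAM_INTERACTOME)
    genes = config.genes
    modules = _plant_module_members(config, rng)

    g = nx.Graph()
    g.add_nodes_from(genes)
    idx = {gene: i for i, gene in enumerate(genes)}
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    background = rng.random(iu.shape[0]) < config.background_edge_prob
    for a, b in zip(iu[background], ju[background]):
        g.add_edge(genes[a], genes[b])
    for members in modules:
        ordered = sorted(members)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                if rng.random() < config.within_module_edge_prob:
                    g.add_edge(a, b)
    # spanning backbone so downstream shortest paths are defined everywhere
    components = sorted(nx.connected_components(g), key=lambda c: min(idx[x] for x in c))
    for prev, nxt in zip(components, components[1:]):
        g.add_edge(min(prev, key=idx.get), min(nxt, key=idx.get))

    truth = SyntheticTruth(planted_modules=modules)
    return g, truth


# ---------------------------------------------------------------------------
# stage expression
# ---------------------------------------------------------------------------

def _shape_classes(n_classes: int, n_stages: int) -> list[tuple[tuple, tuple]]:
    """Distinct step shapes: (breakpoints, step signs), single steps first."""
    shapes: list[tuple[tuple, tuple]] = []
    for bp in range(1, n_stages):
        shapes.append(((bp,), (1,)))
        shapes.append(((bp,), (-1,)))
    for b1 in range(1, n_stages - 1):
        for b2 in range(b1 + 1, n_stages):
            shapes.append(((b1, b2), (1, -1)))
            shapes.append(((b1, b2), (-1, 1)))
    if n_classes > len(shapes):
        raise ValueError(f"cannot build {n_classes} distinct shapes over {n_stages} stages")
    return shapes[:n_classes]


def _assign_changepoints(config: SyntheticConfig, truth: SyntheticTruth,
                         rng: np.random.Generator) -> None:
    genes = config.genes
    if config.changepoint_truth is not None:
        for gene in genes:
            bps = list(config.changepoint_truth.get(gene, []))
            truth.true_changepoints[gene] = bps
            truth.step_signs[gene] = [1] * len(bps)
        return
    if config.n_changepoint_classes:
        shapes = _shape_classes(config.n_changepoint_classes, config.n_stages)
        for i, gene in enumerate(genes):
            cls = i % len(shapes)
            bps, signs = shapes[cls]
            truth.true_changepoints[gene] = list(bps)
            truth.step_signs[gene] = list(signs)
            truth.changepoint_class[gene] = cls
        return
    # default: each planted module switches on at one stage boundary (so
    # modules are enriched in stage-specific DE genes); background genes step
    # at a random boundary with probability de_background_frac — cleavage-to-
    # blastocyst development remodels much of the transcriptome, so a flat
    # background would be unrealistically easy on the multiplicity correction
    assigned: dict[str, int] = {}
    n_boundaries = config.n_stages - 1
    for m, members in enumerate(truth.planted_modules):
        boundary = 1 + (m % n_boundaries)
        for gene in sorted(members):
            assigned.setdefault(gene, boundary)
    for gene in genes:
        if gene in assigned:
            truth.true_changepoints[gene] = [assigned[gene]]
            truth.step_signs[gene] = [1 if rng.random() < 0.5 else -1]
        elif rng.random() < config.de_background_frac:
            truth.true_changepoints[gene] = [int(rng.integers(1, config.n_stages))]
            truth.step_signs[gene] = [1 if rng.random() < 0.5 else -1]
        else:
            truth.true_changepoints[gene] = []
            truth.step_signs[gene] = []


def generate_stage_expression(config: SyntheticConfig, truth: SyntheticTruth) -> ExpressionMatrix:
    """Stage-ordered expression: per-gene step profiles plus Gaussian noise.

    Each gene's stage means form a step function with steps of height
    ``de_effect_size`` (sign recorded in truth) at its planted change points;
    replicate values add N(0, noise_sd).  ``truth.de_genes_per_stage`` maps
    each post-oocyte stage to the genes whose step occurs entering it.
    """
    rng = config.rng(_STREAM_STAGE)
    _assign_changepoints(config, truth, rng)
    genes = config.genes

    baseline = 6.0
    stage_means = np.full((len(genes), config.n_stages), baseline)
    for gi, gene in enumerate(genes):
        steps = dict(zip(truth.true_changepoints[gene], truth.step_signs[gene]))
        level = baseline
        for stage in range(config.n_stages):
            level += steps.get(stage, 0) * config.de_effect_size
            stage_means[gi, stage] = level

    for si, stage in enumerate(config.stage_names[1:], start=1):
        truth.de_genes_per_stage[stage] = {
            g for g in genes if si in truth.true_changepoints[g] and config.de_effect_size > 0
        }

    columns, stages, embryos = [], [], []
    blocks = []
    for si, (stage, nrep) in enumerate(zip(config.stage_names, config.replicates_per_stage)):
        for rep in range(1, nrep + 1):
            columns.append(f"{stage}_{rep}")
            stages.append(stage)
            embryos.append(f"{stage}_{rep}")
        noise = rng.normal(0.0, config.noise_sd, size=(len(genes), nrep)) if config.noise_sd > 0 \
            else np.zeros((len(genes), nrep))
        blocks.append(stage_means[:, [si]] + noise)
    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=columns)
    meta = pd.DataFrame({"stage": stages, "embryo": embryos, "cell": ""}, index=columns)
    return ExpressionMatrix(values, meta)


# ---------------------------------------------------------------------------
# blastomere barcodes, panels, references
# ---------------------------------------------------------------------------

EIF_PANEL = "EIF_EGA"
EPI_PANEL = "EPIGENETIC"


def _pick_blastomere_genes(config: SyntheticConfig) -> dict[str, list[str]]:
    """Deterministic, disjoint gene roles drawn from the tail of the gene list
    (planted interactome modules occupy the head)."""
    genes = config.genes
    need = 2 * config.n_markers_per_group + config.n_housekeeping + config.panel_size
    if need > config.n_genes:
        raise ValueError("infeasible config: not enough genes for marker/panel roles")
    tail = genes[::-1]
    icm = sorted(tail[: config.n_markers_per_group])
    te = sorted(tail[config.n_markers_per_group : 2 * config.n_markers_per_group])
    hk_start = 2 * config.n_markers_per_group
    hk = sorted(tail[hk_start : hk_start + config.n_housekeeping])
    eif = sorted(tail[hk_start + config.n_housekeeping : hk_start + config.n_housekeeping + config.panel_size])
    return {"ICM-like": icm, "TE-like": te, "housekeeping": hk, "eif": eif}


def blastomere_panels(config: SyntheticConfig) -> list[GenePanel]:
    """The two scored panels: graded EIF-style panel and the two-group
    epigenetic marker panel."""
    roles = _pick_blastomere_genes(config)
    epi = roles["ICM-like"][: config.panel_size] + roles["TE-like"][: config.panel_size]
    return [
        GenePanel(EIF_PANEL, frozenset(roles["eif"]), "graded translation-initiation panel"),
        GenePanel(EPI_PANEL, frozenset(epi), "two-group epigenetic marker panel"),
    ]


def generate_blastomere_barcodes(
    config: SyntheticConfig, truth: SyntheticTruth
) -> tuple[ExpressionMatrix, PresenceMatrix]:
    """Single-blastomere intensities with two planted lineage groups.

    Cells split into ICM-like and TE-like halves.  Group markers are drawn
    from the expressed mixture component shifted by ``lineage_separation``
    above the unexpressed mean in their own group and from the unexpressed
    component elsewhere; housekeeping genes are expressed everywhere.  The
    EIF-style panel is fully expressed in ICM-like cells and only partially
    (3 of ``panel_size``) in TE-like cells, mirroring a graded loss of
    translation-initiation expression.  ICM/TE reference profiles are
    appended as labelled samples for embedding/assignment.

    Returns the continuous intensity matrix (blastomeres + references) and
    the true binary barcode over the blastomeres.
    """
    if config.n_blastomeres < 2:
        raise ValueError("need at least 2 blastomeres")
    rng = config.rng(_STREAM_BLASTOMERE)
    genes = config.genes
    cells = config.cells
    half = config.n_blastomeres // 2
    groups = {c: ("ICM-like" if i < config.n_blastomeres - half else "TE-like")
              for i, c in enumerate(cells)}
    truth.blastomere_groups = dict(groups)

    roles = _pick_blastomere_genes(config)
    truth.marker_genes = {"ICM-like": roles["ICM-like"], "TE-like": roles["TE-like"]}
    truth.housekeeping_genes = roles["housekeeping"]
    special = set(roles["ICM-like"]) | set(roles["TE-like"]) | set(roles["housekeeping"]) | set(roles["eif"])

    n_eif_te = max(1, config.panel_size * 3 // 10)  # TE-like cells keep 3/10 of the panel
    eif_te_kept = set(roles["eif"][:n_eif_te])

    # background genes are constitutively on or off (coin flip per gene)
    background_on = {g: bool(rng.random() < 0.5) for g in genes if g not in special}

    def true_call(gene: str, cell: str) -> int:
        grp = groups[cell]
        if gene in truth.marker_genes["ICM-like"]:
            return int(grp == "ICM-like")
        if gene in truth.marker_genes["TE-like"]:
            return int(grp == "TE-like")
        if gene in roles["housekeeping"]:
            return 1
        if gene in roles["eif"]:
            return 1 if grp == "ICM-like" else int(gene in eif_te_kept)
        return int(background_on[gene])

    sample_groups = [(c, groups[c]) for c in cells]
    for ref_i in range(1, config.n_reference_per_class + 1):
        sample_groups.append((f"ICM_ref_{ref_i}", "ICM-like"))
        sample_groups.append((f"TE_ref_{ref_i}", "TE-like"))

    values = np.empty((len(genes), len(sample_groups)))
    barcode = np.zeros((len(genes), len(cells)), dtype=int)
    marker_set = set(roles["ICM-like"]) | set(roles["TE-like"]) | set(roles["eif"])
    for gi, gene in enumerate(genes):
        for si, (sample, grp) in enumerate(sample_groups):
            # markers/panel genes use the delta-shifted component so that
            # lineage_separation=0 collapses the two groups onto one another
            fake_cell = cells[0] if grp == "ICM-like" else cells[-1]
            cell = sample if sample in groups else fake_cell
            present = true_call(gene, cell)
            if gene in marker_set:
                mean = UNEXPRESSED_MEAN + (config.lineage_separation if present else 0.0)
            else:
                mean = EXPRESSED_MEAN if present else UNEXPRESSED_MEAN
            values[gi, si] = rng.normal(mean, INTENSITY_SD)
            if si < len(cells):
                barcode[gi, si] = present

    columns = [s for s, _ in sample_groups]
    stages = ["8cell_blastomere" if s in groups else ("ICM" if s.startswith("ICM") else "TE")
              for s, _ in sample_groups]
    meta = pd.DataFrame(
        {"stage": stages, "embryo": "E1",
         "cell": [s if s in groups else "" for s, _ in sample_groups]},
        index=columns,
    )
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=columns), meta)
    calls = pd.DataFrame(barcode, index=genes, columns=cells)
    truth.true_barcode = {g: {c: int(calls.at[g, c]) for c in cells} for g in genes}

    panels = blastomere_panels(config)
    truth.panel_truth = {
        p.name: {c: int(sum(true_call(g, c) for g in sorted(p.members))) for c in cells}
        for p in panels
    }
    return matrix, PresenceMatrix(calls, provenance="barcode")


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def generate_qpcr(config: SyntheticConfig, truth: SyntheticTruth,
                  genes: list[str] | None = None, n_replicates: int = 3) -> pd.DataFrame:
    """Triplicate Ct table consistent with the planted barcode.

    Expressed (cell, gene) pairs amplify around cycle 28, unexpressed pairs
    around cycle 39.5 (beyond the 37-cycle detection rule).
    """
    if not truth.true_barcode:
        raise ValueError("generate_blastomere_barcodes must run first")
    rng = config.rng(_STREAM_QPCR)
    if genes is None:
        genes = sorted(blastomere_panels(config)[1].members)
    rows = []
    for cell in config.cells:
        for gene in genes:
            expressed = truth.true_barcode[gene][cell]
            mean = 28.0 if expressed else 39.5
            cts = np.clip(rng.normal(mean, 0.5, size=n_replicates), 1.0, 40.0)
            rows.append({"cell": cell, "gene": gene,
                         **{f"ct_rep{i+1}": round(float(ct), 3) for i, ct in enumerate(cts)}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# convenience: whole-study simulation to disk
# ---------------------------------------------------------------------------

def simulate_study(config: SyntheticConfig, outdir: str | Path) -> SyntheticTruth:
    """Generate every synthetic input the pipeline consumes and write it as
    plain text (TSV/GMT/JSON) under ``outdir``."""
    from .io import write_gmt
    from .networks import write_edge_list

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    graph, truth = generate_interactome(config)
    stage = generate_stage_expression(config, truth)
    blasto, barcode = generate_blastomere_barcodes(config, truth)
    qpcr = generate_qpcr(config, truth)

    write_edge_list(graph, out / "interactome.tsv")
    stage.write(out / "stage_expression.tsv", out / "stage_meta.tsv")
    blasto.write(out / "blastomere_expression.tsv", out / "blastomere_meta.tsv")
    barcode.write(out / "true_barcode.tsv")
    write_gmt(blastomere_panels(config), out / "panels.gmt")
    qpcr.to_csv(out / "qpcr.csv", index=False)
    truth.to_json(out / "truth.json")
    return truth
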