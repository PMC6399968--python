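"""End-to-end orchestration: simulate (or load) -> presence/DE -> change
points -> stage networks and modules -> blastomere barcodes, panels and
single-cell networks -> module similarity -> embedding -> consensus lineage
report.

The consensus report formalises the study's narrative synthesis: for each
blastomere four lines of evidence (module-similarity lean, embedding
assignment, EIF-panel count, epigenetic-panel group) vote ICM vs TE; the
majority wins and ties are reported as unresolved.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import barcodes as bc
from . import changepoints as cp
from . import comparison as cmp_
from . import embedding as emb
from . import modules as mod
from . import networks as net
from . import stage_stats as ss
from . import synthetic as syn
from .io import ExpressionMatrix, load_expression, load_gmt

log = logging.getLogger(__name__)

ICM, TE = "ICM", "TE"
UNRESOLVED = "unresolved"


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    simulate: dict | None = None  # SyntheticConfig overrides; None -> load inputs
    inputs: dict | None = None  # paths: stage matrix/meta, blastomere matrix/meta, interactome, panels
    de_threshold: float = 0.05
    presence_fraction: float = 0.75
    presence_threshold: float | None = None  # None -> pooled mixture midpoint
    changepoint_k: int = 7
    changepoint_penalty: float | None = None
    max_stage_modules: int = 15
    max_cell_modules: int = 25
    min_shared_track: int = 3
    min_shared_similar: int = 5
    barcode_min_cells: int = 2
    barcode_max_cells: int = 5
    isomap_k: int = 5
    isomap_d: int = 2
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a simulate block or input paths")
        if self.inputs is not None:
            for key, p in self.inputs.items():
                if not Path(p).exists():
                    raise ValueError(f"input {key!r} does not exist: {p}")
        if not (0 < self.presence_fraction <= 1):
            raise ValueError("presence_fraction must be in (0,1]")
        if self.changepoint_k < 1:
            raise ValueError("changepoint_k must be >= 1")


@dataclass
class ConsensusReport:
    table: pd.DataFrame  # per-cell evidence + consensus
    artifacts: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, index=index)
    return path


def _majority(calls: list[str]) -> str:
    votes = [c for c in calls if c in (ICM, TE)]
    n_icm = votes.count(ICM)
    n_te = votes.count(TE)
    if n_icm > n_te:
        return f"{ICM}-lean"
    if n_te > n_icm:
        return f"{TE}-lean"
    return UNRESOLVED


def run_pipeline(config: PipelineConfig) -> ConsensusReport:
    """Run every stage in dependency order, writing artifacts + manifest.

    Reruns with the same config and seed reproduce identical manifests.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    # ---- stage 1: data ---------------------------------------------------
    if config.simulate is not None:
        scfg = syn.SyntheticConfig(**{"seed": config.seed, **config.simulate})
        graph, truth = syn.generate_interactome(scfg)
        stage_matrix = syn.generate_stage_expression(scfg, truth)
        blasto_matrix, _ = syn.generate_blastomere_barcodes(scfg, truth)
        panels = syn.blastomere_panels(scfg)
        truth.to_json(out / "truth.json")
        written["truth"] = out / "truth.json"
    else:
        paths = config.inputs
        graph = net.load_interactome(paths["interactome"])
        stage_matrix = load_expression(paths["stage_matrix"], paths["stage_meta"])
        blasto_matrix = load_expression(paths["blastomere_matrix"], paths["blastomere_meta"])
        panels = load_gmt(paths["panels"]) if "panels" in paths else []

    stage_matrix.write(out / "stage_expression.tsv", out / "stage_meta.tsv")
    written["stage_expression"] = out / "stage_expression.tsv"

    # ---- stage 2: presence + DE -----------------------------------------
    threshold = config.presence_threshold
    if threshold is None:
        threshold = bc.fit_mixture(stage_matrix.values.to_numpy(float).ravel()).midpoint
    presence, per_stage = ss.call_presence(stage_matrix, threshold=threshold,
                                           stage_fraction=config.presence_fraction)
    de = ss.anova_stage_de(stage_matrix, threshold=config.de_threshold)
    written["de_table"] = _write(de.table.reset_index(names="gene"), out / "de_table.csv")

    # ---- stage 3: change points -----------------------------------------
    cp_genes = sorted(de.de_genes) if de.de_genes else None
    profs, averaged, _ = cp.segment_stage_series(
        stage_matrix, genes=cp_genes, penalty=config.changepoint_penalty)
    k = min(config.changepoint_k, len(averaged))
    groups = cp.cluster_changepoint_groups(averaged, k=k, profiles=profs)
    cp.label_changepoint_groups(groups, per_stage, stage_matrix.stages)
    written["changepoints"] = _write(cp.changepoint_table(profs), out / "changepoints.csv")

    # ---- stage 4: stage networks + modules + tracking -------------------
    stage_module_sets = []
    stages = stage_matrix.stages
    for si, stage in enumerate(stages[1:], start=1):
        de_here = {g for g in de.de_genes if g in per_stage.get(stage, set())}
        seeds = de_here or per_stage.get(stage, set())
        seeds = seeds & set(graph.nodes)
        if len(seeds) < 2:
            log.warning("stage %s: too few seeds, skipped", stage)
            continue
        model = net.infer_network(graph, net.SeedSet(frozenset(seeds)), stage=stage)
        mset = mod.extract_modules(model.graph, max_modules=config.max_stage_modules,
                                   entity=stage)
        stage_module_sets.append(mset)
    if len(stage_module_sets) >= 2:
        links, flags = cmp_.track_modules(stage_module_sets,
                                          min_shared=config.min_shared_track)
        written["module_tracking"] = _write(links, out / "module_tracking.csv")
        written["module_flags"] = _write(flags, out / "module_flags.csv")

    # ---- stage 5: blastomere barcodes + panels --------------------------
    cell_ids = sorted(c for c in blasto_matrix.meta["cell"] if c)
    barcode = bc.call_barcode(blasto_matrix, cells=cell_ids)
    written["barcode"] = out / "barcode.tsv"
    barcode.write(written["barcode"])
    variable = bc.blastomere_variable_filter(barcode, config.barcode_min_cells,
                                             config.barcode_max_cells)

    panel_views = bc.panel_profile(barcode.calls, panels) if panels else {}
    eif_lean: dict[str, str] = {}
    epi_group: dict[str, int] = {}
    if syn.EIF_PANEL in panel_views:
        counts = panel_views[syn.EIF_PANEL].loc["count"]
        median = counts.median()
        eif_lean = {c: (ICM if counts[c] > median else (TE if counts[c] < median else ""))
                    for c in cell_ids}
    if syn.EPI_PANEL in panel_views:
        epi_panel = next(p for p in panels if p.name == syn.EPI_PANEL)
        epi_group = bc.group_cells_by_panel(barcode.calls, epi_panel, k=2)

    # ---- stage 6: embedding + assignment --------------------------------
    ref_labels = {s: st for s, st in blasto_matrix.meta["stage"].items() if st in (ICM, TE)}
    assignment = None
    if ref_labels:
        embedding = emb.isomap_embed(blasto_matrix, k_neighbours=config.isomap_k,
                                     d=config.isomap_d)
        assignment = emb.assign_lineage(embedding, ref_labels, cell_ids)
        written["embedding"] = _write(
            embedding.coordinates.reset_index(names="sample"), out / "embedding.csv")
        written["assignment"] = _write(assignment.reset_index(), out / "assignment.csv")

    # ---- stage 7: single-cell networks + similarity lean ----------------
    sim_lean: dict[str, str] = {}
    if ref_labels:
        ref_calls = bc.call_barcode(blasto_matrix, cells=sorted(ref_labels))
        entities: dict[str, set] = {}
        for cell in cell_ids:
            entities[cell] = {g for g in variable if barcode.calls.at[g, cell] == 1}
        for cls in (ICM, TE):
            members = sorted(s for s, c in ref_labels.items() if c == cls)
            agg = ref_calls.calls[members].mean(axis=1) >= 0.5
            entities[cls] = {g for g in variable if agg.get(g, False)}
        msets = {}
        for name, seeds in entities.items():
            seeds = seeds & set(graph.nodes)
            if len(seeds) < 2:
                continue
            model = net.infer_network(graph, net.SeedSet(frozenset(seeds)), stage=name)
            msets[name] = mod.extract_modules(model.graph,
                                              max_modules=config.max_cell_modules,
                                              entity=name)
        universe = set(graph.nodes)
        sim_rows = []
        for cell in cell_ids:
            if cell not in msets:
                continue
            counts = {}
            for cls in (ICM, TE):
                if cls not in msets:
                    counts[cls] = 0
                    continue
                tab = cmp_.module_similarity(msets[cell], msets[cls], universe,
                                             min_shared=config.min_shared_similar)
                counts[cls] = int(tab.pairs["similar"].sum())
            if counts[ICM] > counts[TE]:
                sim_lean[cell] = ICM
            elif counts[TE] > counts[ICM]:
                sim_lean[cell] = TE
            sim_rows.append({"cell": cell, "similar_to_ICM": counts[ICM],
                             "similar_to_TE": counts[TE],
                             "lean": sim_lean.get(cell, "")})
        if sim_rows:
            written["module_similarity_lean"] = _write(
                pd.DataFrame(sim_rows), out / "module_similarity_lean.csv")

    # ---- stage 8: consensus ---------------------------------------------
    # the epigenetic grouping is unlabelled; orient each group by the
    # majority embedding call among its cells
    epi_lean: dict[str, str] = {}
    if epi_group and assignment is not None:
        for grp in set(epi_group.values()):
            cells_in = [c for c, g in epi_group.items() if g == grp]
            calls = [assignment.loc[c, "call"] for c in cells_in
                     if assignment.loc[c, "call"] in (ICM, TE)]
            if calls:
                lead = ICM if calls.count(ICM) > calls.count(TE) else (
                    TE if calls.count(TE) > calls.count(ICM) else "")
                for c in cells_in:
                    if lead:
                        epi_lean[c] = lead

    rows = []
    for cell in cell_ids:
        evidence = {
            "module_similarity": sim_lean.get(cell, ""),
            "embedding": (assignment.loc[cell, "call"]
                          if assignment is not None and
                          assignment.loc[cell, "call"] in (ICM, TE) else ""),
            "eif_panel": eif_lean.get(cell, ""),
            "epigenetic_group": epi_lean.get(cell, ""),
        }
        consensus = _majority(list(evidence.values()))
        rows.append({"cell": cell, **evidence,
                     "epi_cluster": epi_group.get(cell, ""),
                     "consensus": consensus})
    report_table = pd.DataFrame(rows).set_index("cell")
    written["consensus"] = _write(report_table.reset_index(), out / "consensus.csv")

    manifest = {
        "seed": config.seed,
        "parameters": {k: v for k, v in vars(config).items() if k != "inputs"},
        "artifacts": {k: {"path": str(p), "sha256": _sha256(p)}
                      for k, p in sorted(written.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True,
                                                  default=str))
    return ConsensusReport(report_table, {k: str(v) for k, v in written.items()}, manifest)
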