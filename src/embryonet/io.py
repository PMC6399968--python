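"""Expression matrices, presence matrices and gene panels: loading,
validation, probe collapse and group centering.

Conventions: gene symbols are uppercased and whitespace-stripped on load;
expression values are log-scale microarray intensities or TPM and are never
renormalised here.  Matrices are genes x samples; per-sample metadata carries
at least a ``stage`` label and optionally ``embryo`` and ``cell``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

META_COLUMNS = ("stage", "embryo", "cell")


def normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued matrix with per-sample metadata.

    ``values`` is a DataFrame indexed by gene symbol with sample-id columns;
    ``meta`` is indexed by sample id with columns ``stage`` and optionally
    ``embryo`` / ``cell``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values.index = [normalize_symbol(g) for g in self.values.index]
        self.values.index.name = "gene"
        if self.values.index.duplicated().any():
            dups = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise ValueError(f"duplicate gene symbols after normalization: {dups}")
        if self.values.columns.duplicated().any():
            dups = sorted(set(self.values.columns[self.values.columns.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = [s for s in self.values.columns if s not in self.meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        if "stage" not in self.meta.columns:
            raise ValueError("metadata must have a 'stage' column")
        self.meta = self.meta.loc[list(self.values.columns)]

    # -- accessors ---------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stages(self) -> list[str]:
        """Stage labels in first-appearance sample order."""
        seen: dict[str, None] = {}
        for s in self.meta["stage"]:
            seen.setdefault(s, None)
        return list(seen)

    def samples_of_stage(self, stage: str) -> list[str]:
        return list(self.meta.index[self.meta["stage"] == stage])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)].copy(), self.meta.loc[list(samples)].copy())

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        keep = [normalize_symbol(g) for g in genes]
        return ExpressionMatrix(self.values.loc[keep].copy(), self.meta.copy())

    # -- persistence -------------------------------------------------------
    def write(self, matrix_path: str | Path, meta_path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(matrix_path, sep="\t", index=False)
        meta = self.meta.copy()
        meta.insert(0, "sample", meta.index)
        meta.to_csv(meta_path, sep="\t", index=False)


@dataclass
class PresenceMatrix:
    """Binary present/absent calls, same shape as the source matrix."""

    calls: pd.DataFrame  # genes x samples, int 0/1
    provenance: str = "threshold-based"  # flag-based | threshold-based | barcode

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("presence calls must be 0/1")
        self.calls = self.calls.astype(int)

    def write(self, path: str | Path) -> None:
        out = self.calls.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(path, sep="\t", index=False)


@dataclass
class GenePanel:
    """A named gene set (e.g. the EIF family or epigenetic regulators)."""

    name: str
    members: frozenset = field(default_factory=frozenset)
    description: str = ""

    def __post_init__(self) -> None:
        members = frozenset(normalize_symbol(g) for g in self.members)
        if not members:
            raise ValueError(f"panel {self.name!r} is empty")
        self.members = members


def load_expression(matrix_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Load a TSV expression matrix (first column ``gene``) and its metadata.

    Every sample column must appear in the metadata; duplicate symbols after
    uppercasing are rejected.
    """
    values = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    gene_col = values.columns[0]
    values = values.set_index(gene_col)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    sample_col = meta.columns[0]
    if meta[sample_col].duplicated().any():
        dups = sorted(set(meta[sample_col][meta[sample_col].duplicated()]))
        raise ValueError(f"duplicate sample id in metadata: {dups}")
    meta = meta.set_index(sample_col)
    return ExpressionMatrix(values.astype(float), meta)


def load_gmt(path: str | Path) -> list[GenePanel]:
    """Read gene panels from a standard GMT file (name, description, members)."""
    panels = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        panels.append(GenePanel(parts[0], frozenset(p for p in parts[2:] if p.strip()), parts[1]))
    return panels


def write_gmt(panels: list[GenePanel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in panels:
            fh.write("\t".join([p.name, p.description, *sorted(p.members)]) + "\n")


def load_probe_map(path: str | Path) -> dict[str, str]:
    """Probe -> gene symbol TSV (two columns, header optional)."""
    mapping: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        probe, gene = line.split("\t")[:2]
        if i == 0 and probe.lower() in ("probe", "probe_id"):
            continue
        mapping[probe.strip()] = normalize_symbol(gene)
    if not mapping:
        raise ValueError("empty probe map")
    return mapping


def collapse_probes(matrix: ExpressionMatrix, probe_to_gene: dict[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene by per-sample maximum.

    Probes absent from the map are dropped (count logged).  Idempotent on
    gene-level matrices under an identity map.
    """
    if not probe_to_gene:
        raise ValueError("empty probe map")
    mapped = {p: normalize_symbol(g) for p, g in probe_to_gene.items()}
    keep = [p for p in matrix.values.index if p in mapped]
    dropped = len(matrix.values.index) - len(keep)
    if dropped:
        log.info("collapse_probes: dropped %d unmapped probes", dropped)
    if not keep:
        raise ValueError("no probes remain after mapping")
    sub = matrix.values.loc[keep]
    collapsed = sub.groupby([mapped[p] for p in keep], sort=False).max()
    collapsed.index.name = "gene"
    return ExpressionMatrix(collapsed, matrix.meta.copy())


def center_by_group(matrix: ExpressionMatrix, group_key: str = "embryo") -> ExpressionMatrix:
    """Subtract, per gene, the mean over each metadata group's samples.

    Used to remove embryo-of-origin (donor-couple) shifts before comparing
    single blastomeres; after centering each group's per-gene mean is 0.
    """
    if group_key not in matrix.meta.columns:
        raise ValueError(f"metadata lacks group key {group_key!r}")
    if matrix.meta[group_key].isna().any():
        raise ValueError(f"group key {group_key!r} missing for some samples")
    values = matrix.values.copy()
    for _, samples in matrix.meta.groupby(group_key, sort=False).groups.items():
        cols = list(samples)
        if len(cols) == 1:
            log.warning("center_by_group: group with a single sample %s", cols)
        block = values[cols]
        values[cols] = block.sub(block.mean(axis=1), axis=0)
    return ExpressionMatrix(values, matrix.meta.copy())
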