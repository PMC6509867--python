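"""Readers and preprocessing for omics, clinical, PPI and GMT inputs.

Implements the pipeline's data model: cleaned per-layer omics matrices, the
standardized concatenated feature matrix X, one-vs-rest binary stage label
vectors, the undirected PPI graph and named gene-set collections. Filtering
rules: features with any NA/NULL value are dropped; methylation loci mapped
to multiple genes are shared equally among them; samples without a usable
``pathology_t_stage`` are excluded; substage suffixes (t2a, T2b) normalize
to their major stage.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IngestError",
    "OmicsParseError",
    "OmicsLayer",
    "FeatureMatrix",
    "StageLabelVector",
    "read_omics",
    "intersect_layers",
    "binarize_stages",
    "assemble_features",
    "read_ppi",
    "read_gmt",
    "write_ppi",
]

STAGES = ("t1", "t2", "t3", "t4")


class IngestError(ValueError):
    """Input violates a documented contract (empty intersection, bad stage...)."""


class OmicsParseError(IngestError):
    """Malformed omics/PPI/GMT file; message names the offending row or line."""


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


@dataclass
class OmicsLayer:
    """One omics layer: samples x features values plus gene provenance."""

    values: pd.DataFrame  # samples x features
    gene_of_feature: dict[str, str]
    layer: str  # "expression" | "methylation"

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_of_feature.values())


@dataclass
class FeatureMatrix:
    """Standardized design matrix X with per-column gene/layer provenance."""

    X: np.ndarray  # m x n, each column z-scored
    sample_ids: list[str]
    column_gene: list[str]
    column_layer: list[str]

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    def columns_of_gene(self, gene: str) -> list[int]:
        return [j for j, g in enumerate(self.column_gene) if g == gene]

    @property
    def genes(self) -> set[str]:
        return set(self.column_gene)


@dataclass
class StageLabelVector:
    """One-vs-rest binary labels Y_t for a single pathology stage."""

    stage: str
    y: np.ndarray  # binary, length m
    sample_ids: list[str] = field(default_factory=list)


_NA_TOKENS = {"na", "null", "nan", ""}


def read_omics(
    path: str | Path,
    layer: str,
    locus_map: dict[str, Iterable[str]] | None = None,
) -> OmicsLayer:
    """Read a features-x-samples TSV matrix into a cleaned :class:`OmicsLayer`.

    Features containing any NA/NULL value are filtered out. If ``locus_map``
    is given (methylation CpG loci annotated to gene sets), each locus value
    is divided equally among its mapped genes and a gene's value is the mean
    of its locus contributions; the returned features are then per-gene.
    """
    path = Path(path)
    with _open_text(path) as fh:
        try:
            df = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
        except pd.errors.EmptyDataError:
            raise OmicsParseError(f"{path}: empty file") from None
    if df.empty and len(df.columns) == 0:
        raise OmicsParseError(f"{path}: empty file")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise OmicsParseError(f"{path}: duplicate feature IDs {dupes[:5]}")

    cleaned = df.apply(lambda col: col.str.strip())
    is_na = cleaned.isna() | cleaned.apply(lambda col: col.str.lower().isin(_NA_TOKENS))
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for feat in df.index:
        row = cleaned.loc[feat]
        mask = is_na.loc[feat]
        try:
            numeric.loc[feat] = pd.to_numeric(row.where(~mask))
        except (ValueError, TypeError) as exc:
            raise OmicsParseError(f"{path}: non-numeric cell in feature row '{feat}': {exc}") from None

    keep = ~is_na.any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: dropped %d/%d features with missing values", path.name, dropped, len(df))
    numeric = numeric.loc[keep]

    values = numeric.T  # samples x features
    if locus_map is not None:
        values, gene_of_feature = _share_loci(values, locus_map)
    else:
        gene_of_feature = {f: f for f in values.columns}
    return OmicsLayer(values=values, gene_of_feature=gene_of_feature, layer=layer)


def _share_loci(
    values: pd.DataFrame, locus_map: dict[str, Iterable[str]]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Split each locus equally among its genes, then average per gene.

    A locus annotated to g genes contributes value/g to each; a gene's value
    is the mean of the contributions of its loci. Loci absent from the map
    are dropped with a log message.
    """
    contrib: dict[str, list[pd.Series]] = {}
    missing = 0
    for locus in values.columns:
        genes = sorted(set(locus_map.get(locus, ())))
        if not genes:
            missing += 1
            continue
        share = values[locus] / len(genes)
        for g in genes:
            contrib.setdefault(g, []).append(share)
    if missing:
        logger.info("dropped %d loci absent from the locus map", missing)
    per_gene = {g: sum(parts) / len(parts) for g, parts in contrib.items()}
    out = pd.DataFrame(per_gene, index=values.index).sort_index(axis=1)
    return out, {g: g for g in out.columns}


def intersect_layers(expr: OmicsLayer, meth: OmicsLayer) -> tuple[OmicsLayer, OmicsLayer]:
    """Restrict both layers to genes measured in both, in identical order."""
    shared = sorted(expr.genes & meth.genes)
    if not shared:
        raise IngestError("no shared genes between expression and methylation layers")

    def restrict(layer: OmicsLayer) -> OmicsLayer:
        keep = [f for f in layer.feature_ids if layer.gene_of_feature[f] in set(shared)]
        order = sorted(keep, key=lambda f: (layer.gene_of_feature[f], f))
        return OmicsLayer(
            values=layer.values[order],
            gene_of_feature={f: layer.gene_of_feature[f] for f in order},
            layer=layer.layer,
        )

    return restrict(expr), restrict(meth)


def normalize_stage(raw: object) -> str | None:
    """Normalize a pathology_t_stage value: 'T2b' -> 't2'; None if missing."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip().lower()
    if not s or s in _NA_TOKENS:
        return None
    return s.rstrip("abcdefghijklmnopqrstuvwxyz") if len(s) > 1 else s


def binarize_stages(
    clinical: pd.DataFrame, stages: Iterable[str] = STAGES
) -> list[StageLabelVector]:
    """One-vs-rest binary label vectors per stage from the clinical table.

    Samples with a missing stage are dropped; substage suffixes are stripped.
    A value outside the stage list after normalization raises, naming the
    offending samples.
    """
    stages = list(stages)
    if "sample_id" not in clinical.columns or "pathology_t_stage" not in clinical.columns:
        raise IngestError("clinical table needs 'sample_id' and 'pathology_t_stage' columns")

    kept: list[tuple[str, str]] = []
    bad: list[str] = []
    for _, row in clinical.iterrows():
        st = normalize_stage(row["pathology_t_stage"])
        if st is None:
            continue
        if st not in stages:
            bad.append(str(row["sample_id"]))
            continue
        kept.append((str(row["sample_id"]), st))
    if bad:
        raise IngestError(f"stage value outside {stages} for samples: {bad}")
    if not kept:
        raise IngestError("no samples with a usable pathology_t_stage")

    sample_ids = [s for s, _ in kept]
    labels = np.array([st for _, st in kept])
    return [
        StageLabelVector(stage=st, y=(labels == st).astype(float), sample_ids=sample_ids)
        for st in stages
    ]


def assemble_features(
    expr: OmicsLayer, meth: OmicsLayer, sample_ids: list[str]
) -> FeatureMatrix:
    """Concatenate expression then methylation features and z-score columns.

    Constant columns are dropped with a warning. Every requested sample must
    be present in both layers.
    """
    for layer in (expr, meth):
        missing = [s for s in sample_ids if s not in layer.values.index]
        if missing:
            raise IngestError(f"samples missing from {layer.layer} layer: {missing[:5]}")

    blocks, col_gene, col_layer = [], [], []
    for layer in (expr, meth):
        sub = layer.values.loc[sample_ids]
        blocks.append(sub.to_numpy(dtype=float))
        col_gene.extend(layer.gene_of_feature[f] for f in sub.columns)
        col_layer.extend(layer.layer for _ in sub.columns)
    X = np.hstack(blocks)

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd < 1e-12
    if constant.any():
        logger.warning("dropping %d constant feature columns", int(constant.sum()))
    keep = ~constant
    X = (X[:, keep] - mean[keep]) / sd[keep]
    col_gene = [g for g, k in zip(col_gene, keep) if k]
    col_layer = [l for l, k in zip(col_layer, keep) if k]
    if X.shape[1] == 0:
        raise IngestError("all feature columns constant; nothing to model")
    return FeatureMatrix(X=X, sample_ids=list(sample_ids), column_gene=col_gene, column_layer=col_layer)


def read_ppi(path: str | Path) -> nx.Graph:
    """Read a two-column TSV edge list into a simple undirected graph.

    Duplicate edges and self-loops are dropped and counted in the log.
    """
    path = Path(path)
    g = nx.Graph()
    self_loops = dupes = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise OmicsParseError(f"{path}: malformed PPI line {lineno}: {line!r}")
            u, v = parts[0].strip(), parts[1].strip()
            if u == v:
                self_loops += 1
                continue
            if g.has_edge(u, v):
                dupes += 1
                continue
            g.add_edge(u, v)
    if self_loops or dupes:
        logger.info("%s: dropped %d self-loops, %d duplicate edges", path.name, self_loops, dupes)
    return g


def write_ppi(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{u}\t{v}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a standard GMT file (name, description, members...) into sets.

    Duplicate members within a set are removed.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise OmicsParseError(f"{path}: malformed GMT line {lineno} (needs >=3 fields)")
            name = parts[0].strip()
            if not name:
                raise OmicsParseError(f"{path}: empty set name at GMT line {lineno}")
            members = {p.strip() for p in parts[2:] if p.strip()}
            sets[name] = members
    return sets
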