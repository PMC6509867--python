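"""Synthetic multi-omics inputs with planted stage-specific structure.

This module generates the five inputs the pipeline consumes — paired
expression/methylation matrices, a clinical staging table, an undirected
protein–protein interaction (PPI) edge list and a GMT pathway collection —
together with the ground truth that was planted into them. Each stage t
receives a set of "planted" signal genes whose expression is shifted upward
(and methylation downward, mimicking the canonical promoter-methylation /
expression anti-correlation) in samples of that stage; planted genes are
wired into connected PPI neighborhoods and seeded into enriched pathways so
that every downstream step of the pipeline has recoverable signal.

All generation is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SynthConfig", "SynthTruth", "gen_omics", "gen_ppi", "gen_pathways", "write_inputs"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults describe the reference simulation used throughout the test
    suite: 200 tumor samples over 4 pathology stages, 500 genes of which 10
    per stage carry signal, a standardized mean shift of 2 against unit
    noise, an HPRD-like sparse PPI graph and a 50-set pathway collection.
    """

    n_samples: int = 200
    n_genes: int = 500
    n_stages: int = 4
    signal_genes_per_stage: int = 10
    effect_size: float = 2.0
    noise_sd: float = 1.0
    ppi_mean_degree: float = 8.0
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 40)
    seed: int = 0
    #: per-stage sample proportions; None means uniform
    stage_proportions: tuple[float, ...] | None = None
    #: fraction of pathways seeded with planted genes of one stage
    signal_pathway_fraction: float = 0.5
    #: fraction of a signal pathway's members drawn from its stage's planted genes
    signal_pathway_planted_fraction: float = 0.6
    #: genes shared between signal pathways of consecutive stages
    n_shared_pathway_genes: int = 3
    #: use preferential attachment instead of uniform random background edges
    scale_free: bool = False

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_stages", "signal_genes_per_stage"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_pathways < 0:
            raise ValueError("n_pathways must be >= 0")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValueError("pathway_size_range must satisfy 1 <= min <= max <= n_genes")
        if self.stage_proportions is not None:
            if len(self.stage_proportions) != self.n_stages:
                raise ValueError("stage_proportions length must equal n_stages")
            if abs(sum(self.stage_proportions) - 1.0) > 1e-9:
                raise ValueError("stage proportions must sum to 1")
        if self.signal_genes_per_stage * self.n_stages > self.n_genes:
            raise ValueError("gene universe too small")
        if self.ppi_mean_degree >= self.n_genes:
            raise ValueError("ppi_mean_degree must be < n_genes")

    @property
    def stages(self) -> list[str]:
        return [f"t{i + 1}" for i in range(self.n_stages)]

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def sample_ids(self) -> list[str]:
        width = len(str(self.n_samples))
        return [f"S{i:0{width}d}" for i in range(1, self.n_samples + 1)]


@dataclass
class SynthTruth:
    """Ground truth planted by the generator, for parameter-recovery tests."""

    planted_genes: dict[str, set[str]]
    stage_of_sample: dict[str, str]
    pathway_membership: dict[str, set[str]] = field(default_factory=dict)
    #: pathways deliberately enriched for one stage's planted genes
    signal_pathways: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "planted_genes": {s: sorted(g) for s, g in self.planted_genes.items()},
            "stage_of_sample": self.stage_of_sample,
            "pathway_membership": {p: sorted(g) for p, g in self.pathway_membership.items()},
            "signal_pathways": self.signal_pathways,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SynthTruth":
        d = json.loads(text)
        return cls(
            planted_genes={s: set(g) for s, g in d["planted_genes"].items()},
            stage_of_sample=d["stage_of_sample"],
            pathway_membership={p: set(g) for p, g in d["pathway_membership"].items()},
            signal_pathways=d.get("signal_pathways", {}),
        )


def _rng(cfg: SynthConfig, stream: str) -> np.random.Generator:
    # independent, reproducible stream per artifact so regenerating one does
    # not perturb the others; crc32 is stable across processes (unlike hash())
    tag = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, tag]))


def gen_omics(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SynthTruth]:
    """Generate paired expression/methylation matrices and a clinical table.

    Returns (expression, methylation, clinical, truth). The omics frames are
    features x samples (gene rows, sample columns) on a z-score-like scale:
    background entries are N(0, noise_sd²) and, for samples of stage t, the
    planted genes of t are shifted by +effect_size in expression and
    −effect_size in methylation. The clinical frame has columns
    ``sample_id`` and ``pathology_t_stage``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes, samples, stages = cfg.gene_ids, cfg.sample_ids, cfg.stages

    props = cfg.stage_proportions or tuple(1.0 / cfg.n_stages for _ in stages)
    counts = np.floor(np.asarray(props) * cfg.n_samples).astype(int)
    # distribute the remainder deterministically over the earliest stages
    for i in range(cfg.n_samples - counts.sum()):
        counts[i % cfg.n_stages] += 1
    stage_labels = np.repeat(stages, counts)
    rng.shuffle(stage_labels)
    stage_of_sample = dict(zip(samples, stage_labels))

    perm = rng.permutation(cfg.n_genes)
    planted: dict[str, set[str]] = {}
    for i, st in enumerate(stages):
        idx = perm[i * cfg.signal_genes_per_stage : (i + 1) * cfg.signal_genes_per_stage]
        planted[st] = {genes[j] for j in idx}

    expr = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_samples))
    meth = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_samples))
    gene_index = {g: i for i, g in enumerate(genes)}
    for st in stages:
        cols = np.flatnonzero(stage_labels == st)
        rows = np.array(sorted(gene_index[g] for g in planted[st]))
        expr[np.ix_(rows, cols)] += cfg.effect_size
        meth[np.ix_(rows, cols)] -= cfg.effect_size

    expression = pd.DataFrame(expr, index=genes, columns=samples)
    methylation = pd.DataFrame(meth, index=genes, columns=samples)
    clinical = pd.DataFrame({"sample_id": samples, "pathology_t_stage": stage_labels})
    truth = SynthTruth(planted_genes=planted, stage_of_sample=stage_of_sample)
    return expression, methylation, clinical, truth


def gen_ppi(cfg: SynthConfig, truth: SynthTruth) -> list[tuple[str, str]]:
    """Generate a simple undirected PPI edge list over the gene universe.

    Planted genes of each stage are wired to a stage hub (the
    lexicographically first planted gene), making them mutually reachable
    within two hops, then background edges are added by uniform random
    attachment (or preferential attachment when ``cfg.scale_free``) until
    the expected mean degree is met. No self-loops, no duplicate edges.
    """
    rng = _rng(cfg, "ppi")
    genes = cfg.gene_ids
    edges: set[tuple[str, str]] = set()

    def add(u: str, v: str) -> None:
        if u != v:
            edges.add((u, v) if u < v else (v, u))

    for st in sorted(truth.planted_genes):
        members = sorted(truth.planted_genes[st])
        if len(members) < 2:
            continue
        hub = members[0]
        for g in members[1:]:
            add(hub, g)

    target = int(round(cfg.ppi_mean_degree * cfg.n_genes / 2.0))
    if cfg.scale_free:
        degree = {g: 1.0 for g in genes}  # +1 smoothing so isolated genes stay reachable
        gene_arr = np.array(genes)
        while len(edges) < target:
            w = np.array([degree[g] for g in genes])
            u, v = rng.choice(gene_arr, size=2, replace=False, p=w / w.sum())
            before = len(edges)
            add(u, v)
            if len(edges) > before:
                degree[u] += 1
                degree[v] += 1
    else:
        gene_arr = np.array(genes)
        while len(edges) < target:
            # draw in batches; duplicates and self-loops collapse in the set
            need = max(target - len(edges), 1)
            pairs = rng.integers(0, cfg.n_genes, size=(need * 2, 2))
            for i, j in pairs:
                if len(edges) >= target:
                    break
                add(gene_arr[i], gene_arr[j])
    return sorted(edges)


def gen_pathways(cfg: SynthConfig, truth: SynthTruth) -> dict[str, set[str]]:
    """Generate a GMT-style pathway collection and record it in ``truth``.

    A configurable fraction of pathways are "signal" pathways assigned
    round-robin to stages and seeded with that stage's planted genes; signal
    pathways of consecutive stages additionally share a few member genes so
    the downstream pathway network contains cross-stage edges. Remaining
    pathways are uniform random gene sets.
    """
    rng = _rng(cfg, "pathways")
    genes = np.array(cfg.gene_ids)
    stages = cfg.stages
    lo, hi = cfg.pathway_size_range
    n_signal = int(round(cfg.signal_pathway_fraction * cfg.n_pathways))

    pathways: dict[str, set[str]] = {}
    signal_pathways: dict[str, list[str]] = {st: [] for st in stages}
    width = max(2, len(str(max(cfg.n_pathways, 1))))

    for i in range(cfg.n_pathways):
        name = f"PW{i + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        if i < n_signal:
            st = stages[i % len(stages)]
            pool = sorted(truth.planted_genes[st])
            # cap signal-pathway size so planted members are a majority
            size = max(lo, min(size, 2 * len(pool)))
            n_planted = min(len(pool), max(1, int(np.ceil(cfg.signal_pathway_planted_fraction * size))))
            chosen = set(rng.choice(pool, size=n_planted, replace=False))
            background = genes[~np.isin(genes, sorted(chosen))]
            filler = rng.choice(background, size=size - len(chosen), replace=False)
            pathways[name] = chosen | set(filler)
            signal_pathways[st].append(name)
        else:
            pathways[name] = set(rng.choice(genes, size=size, replace=False))

    # make consecutive-stage signal pathways share members: copy a few genes
    # from the first signal pathway of stage t into that of stage t+1
    for a, b in zip(stages, stages[1:]):
        if not signal_pathways[a] or not signal_pathways[b]:
            continue
        src, dst = signal_pathways[a][0], signal_pathways[b][0]
        donate = sorted(pathways[src] - pathways[dst])[: cfg.n_shared_pathway_genes]
        pathways[dst] |= set(donate)

    truth.pathway_membership = {k: set(v) for k, v in pathways.items()}
    truth.signal_pathways = signal_pathways
    return pathways


def write_inputs(cfg: SynthConfig, outdir: str | Path) -> SynthTruth:
    """Generate everything and write the pipeline's five input files.

    Writes expression.tsv, methylation.tsv (features x samples), clinical.tsv,
    ppi.tsv, pathways.gmt and truth.json under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expression, methylation, clinical, truth = gen_omics(cfg)
    edges = gen_ppi(cfg, truth)
    pathways = gen_pathways(cfg, truth)

    expression.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene", float_format="%.6g")
    methylation.to_csv(outdir / "methylation.tsv", sep="\t", index_label="gene", float_format="%.6g")
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    with open(outdir / "ppi.tsv", "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")
    with open(outdir / "pathways.gmt", "w") as fh:
        for name in sorted(pathways):
            members = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\tsynthetic pathway\t{members}\n")
    (outdir / "truth.json").write_text(truth.to_json())
    (outdir / "config.json").write_text(json.dumps(dataclasses.asdict(cfg), indent=2))
    return truth
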